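"""Epiallele classification, genotyping and promoter-state calling."""

import itertools

import numpy as np
import pytest

import helpers
from allelobis import fixtures, pipeline
from allelobis.patterns import (
    EpialleleClass,
    allele_methylation_association,
    build_profile,
    call_genotype,
    classify_clone,
    classify_promoter_state,
)
from allelobis.pipeline import CloneReport, SiteCall
from allelobis.reference import MethylSite


def _site(position, context="CpG", proximal=False):
    return MethylSite(position=position, context=context, motif_start=position,
                      tss_label=position + 1, proximal_pair_member=proximal)


def _clone_report(cpg_states, ccwgg_states=(), allele="A", clone_id="c",
                  proximal_flags=None):
    calls = [
        SiteCall(_site(i), s, {"methylated": "C", "unmethylated": "T"}.get(s, "N"))
        for i, s in enumerate(cpg_states)
    ]
    proximal_flags = proximal_flags or [False] * len(ccwgg_states)
    calls += [
        SiteCall(_site(100 + i, "CCWGG", prox), s,
                 {"methylated": "C", "unmethylated": "T"}.get(s, "N"))
        for i, (s, prox) in enumerate(zip(ccwgg_states, proximal_flags))
    ]
    return CloneReport(clone_id=clone_id, site_calls=calls, conversion_efficiency=1.0,
                       n_converted_c=50, n_eligible_c=50, passes_qc=True, allele=allele)


def _states(bits):
    return ["methylated" if b else "unmethylated" for b in bits]


def _oracle_class(cpg_bits, n_ccwgg_meth, full_threshold=0.9):
    """Direct restatement of the classification rule, kept trivially simple."""
    f = sum(cpg_bits) / len(cpg_bits)
    if f == 0 and n_ccwgg_meth == 0:
        return "unmethylated"
    if f >= full_threshold and n_ccwgg_meth == 0:
        return "cg_only_methylated"
    if f >= full_threshold:
        return "cg_ccwgg_methylated"
    return "partial"


class TestClassifyClone:
    def test_fully_methylated_with_proximal_pair(self):
        report = _clone_report(_states([1] * 6), _states([1] * 5),
                               proximal_flags=[True, True, False, False, False])
        cls = classify_clone(report)
        assert cls.value == "cg_ccwgg_methylated" and cls.proximal_pair_methylated

    def test_zero_methylation_is_unmethylated(self):
        assert classify_clone(_clone_report(_states([0] * 6), _states([0] * 5))).value == (
            "unmethylated"
        )

    def test_half_methylated_is_partial(self):
        assert classify_clone(_clone_report(_states([1, 1, 1, 0, 0, 0]))).value == "partial"

    def test_one_ambiguous_site_does_not_demote_full_clone(self):
        states = _states([1] * 5) + ["ambiguous"]
        assert classify_clone(_clone_report(states)).value == "cg_only_methylated"

    def test_all_cpg_ambiguous_is_indeterminate(self):
        assert classify_clone(_clone_report(["ambiguous"] * 6)).value == "indeterminate"

    @pytest.mark.parametrize("n_ccwgg_meth", [0, 1])
    def test_exhaustive_enumeration_of_all_cpg_vectors(self, n_ccwgg_meth):
        # all 2^6 CpG state vectors against the brute-force rule oracle
        for bits in itertools.product([0, 1], repeat=6):
            report = _clone_report(_states(bits), _states([1] * n_ccwgg_meth))
            assert classify_clone(report).value == _oracle_class(bits, n_ccwgg_meth), bits

    @pytest.mark.parametrize("n_sites", [4, 8])
    def test_exhaustive_enumeration_other_site_counts(self, n_sites):
        for bits in itertools.product([0, 1], repeat=n_sites):
            report = _clone_report(_states(bits))
            assert classify_clone(report).value == _oracle_class(bits, 0)


class TestCallGenotype:
    def _reports(self, alleles):
        return [_clone_report(_states([0] * 6), allele=a, clone_id=f"c{i}")
                for i, a in enumerate(alleles)]

    def test_het_from_balanced_support(self):
        genotype, alleles = call_genotype(self._reports(["A"] * 11 + ["G"] * 5), ("G", "A"))
        assert genotype == "het" and alleles == ("G", "A")

    def test_hom_from_unanimous_support(self):
        genotype, alleles = call_genotype(self._reports(["A"] * 20), ("G", "A"))
        assert genotype == "hom_alt" and alleles == ("A",)

    def test_single_minor_clone_treated_as_error(self):
        genotype, alleles = call_genotype(self._reports(["A"] * 19 + ["G"]), ("G", "A"))
        assert genotype == "hom_alt" and alleles == ("A",)

    def test_undetermined_without_phased_clones(self):
        genotype, _ = call_genotype(self._reports(["undetermined"] * 5), ("G", "A"))
        assert genotype == "undetermined"

    def test_minor_fraction_threshold(self):
        # 2 of 30 clones = 6.7% < 10% minor fraction -> homozygous
        genotype, _ = call_genotype(self._reports(["A"] * 28 + ["G"] * 2), ("G", "A"))
        assert genotype == "hom_alt"


class TestAssociation:
    @pytest.mark.parametrize(
        "table",
        [[[8, 0], [0, 5]], [[5, 5], [5, 5]], [[3, 8], [9, 2]], [[1, 9], [7, 4]]],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert allele_methylation_association(table) == pytest.approx(
            helpers.fisher_two_sided(table)
        )

    def test_no_association_gives_p_one(self):
        assert allele_methylation_association([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_empty_margin_undefined(self):
        assert allele_methylation_association([[1, 0], [0, 0]]) is None


def _cls(value, f=None, n_cpg=0, n_ccwgg=0, pair=False):
    return EpialleleClass(value, pair, f, n_cpg, n_ccwgg)


class TestClassifyPromoterState:
    def test_fewer_than_six_clones_is_indeterminate(self):
        clones = [("A", _cls("unmethylated", 0.0))] * 2
        assert classify_promoter_state("het", clones) == "indeterminate"

    def test_snp_phased_monoallelic_with_cg_only_minority(self):
        clones = (
            [("A", _cls("unmethylated", 0.0))] * 8
            + [("G", _cls("cg_ccwgg_methylated", 1.0, 6, 5, pair=True))] * 5
            + [("A", _cls("cg_only_methylated", 1.0, 6))] * 3
        )
        assert classify_promoter_state("het", clones) == "monoallelic_methylation"

    def test_discordant_clones_break_rule_one(self):
        # 4 unmethylated clones on the methylated allele exceed the
        # discordance allowance and dilute the bimodal fallback too
        clones = (
            [("A", _cls("unmethylated", 0.0))] * 10
            + [("G", _cls("cg_ccwgg_methylated", 1.0, 6, 5))] * 4
            + [("G", _cls("unmethylated", 0.0))] * 4
        )
        assert classify_promoter_state("het", clones) != "monoallelic_methylation"

    def test_biallelic_methylated(self):
        clones = [("A", _cls("cg_only_methylated", 1.0, 6))] * 20
        assert classify_promoter_state("hom_alt", clones) == "biallelic_methylated"

    def test_biallelic_unmethylated(self):
        clones = [("A", _cls("unmethylated", 0.0))] * 20
        assert classify_promoter_state("hom_alt", clones) == "biallelic_unmethylated"

    def test_pattern_based_monoallelic_for_homozygous_sample(self):
        clones = (
            [("A", _cls("unmethylated", 0.0))] * 10
            + [("A", _cls("cg_ccwgg_methylated", 1.0, 6, 2, pair=True))] * 10
        )
        assert classify_promoter_state("hom_alt", clones) == "monoallelic_methylation"

    def test_stochastic_biallelic(self):
        clones = [
            ("A" if i % 2 else "G", _cls("partial", (i % 4 + 1) / 6, i % 4 + 1))
            for i in range(16)
        ]
        assert classify_promoter_state("het", clones) == "stochastic_biallelic"


class TestFixtureProfiles:
    EXPECTED = {
        "HPrEpiC": ("het", "stochastic_biallelic"),
        "BPH1": ("het", "monoallelic_methylation"),
        "LNCaP": ("hom_alt", "biallelic_unmethylated"),
        "PC3": ("hom_alt", "biallelic_methylated"),
        "PA1": ("hom_alt", "monoallelic_methylation"),
    }

    @pytest.mark.parametrize("sample", sorted(EXPECTED))
    def test_states_and_genotypes(self, sample, gdna_datasets, region):
        dataset = gdna_datasets[sample]
        passed, omitted = pipeline.process_clones(dataset.reads, region)
        profile = build_profile(sample, passed, omitted, region.snp.alleles)
        genotype, state = self.EXPECTED[sample]
        assert profile.genotype == genotype
        assert profile.promoter_state == state
        assert profile.n_passed == len(dataset.reads)

    def test_bph1_clone_count_breakdown(self, gdna_datasets, region):
        dataset = gdna_datasets["BPH1"]
        passed, omitted = pipeline.process_clones(dataset.reads, region)
        profile = build_profile("BPH1", passed, omitted, region.snp.alleles)
        assert profile.clone_counts == {
            ("A", "unmethylated"): 8,
            ("G", "cg_ccwgg_methylated"): 5,
            ("A", "cg_only_methylated"): 3,
        }
        assert profile.association_p is not None


class TestStateRecovery:
    """Promoter-state recovery from re-simulated samples (smaller sweep here;
    the full 200-seed sweep runs in the acceptance suite)."""

    @pytest.mark.parametrize("sample", sorted(TestFixtureProfiles.EXPECTED))
    def test_zero_noise_recovery_is_exact(self, sample, region):
        expected = TestFixtureProfiles.EXPECTED[sample][1]
        for seed in range(10):
            dataset = fixtures.load_sample(sample, seed=seed)
            passed, omitted = pipeline.process_clones(dataset.reads, region)
            profile = build_profile(sample, passed, omitted, region.snp.alleles)
            assert profile.promoter_state == expected
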