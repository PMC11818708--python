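"""Reference model: motif scanning, in-silico conversion, TSS labelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from allelobis.reference import (
    CCWGG,
    CPG,
    ConfigurationError,
    MotifSpec,
    ReferenceRegion,
    SnpSpec,
    alignment_reference,
    convert_insilico,
    position_from_tss_label,
    scan_motifs,
    tss_label,
)


def _region(sequence, tss=0, window=None, **kw):
    return ReferenceRegion("test", sequence, tss, window or (0, len(sequence)), **kw)


class TestScanMotifs:
    def test_single_cpg(self):
        sites = scan_motifs(_region("AACGTT"), CPG)
        assert [(s.position, s.motif_start) for s in sites] == [(2, 2)]

    def test_ccwgg_internal_c_is_assayed(self):
        sites = scan_motifs(_region("CCACCAGG"), CCWGG)
        assert [(s.motif_start, s.position) for s in sites] == [(3, 4)]
        assert helpers.ccwgg_internal_c_positions("CCACCAGG") == [4]

    def test_overlapping_occurrences_all_reported(self):
        # CGCG carries two overlapping-context CG occurrences
        sites = scan_motifs(_region("ACGCGT"), CPG)
        assert [s.position for s in sites] == [1, 3]

    def test_window_excludes_outside_sites(self):
        region = _region("CGAACGAACG", window=(3, 8))
        assert [s.position for s in scan_motifs(region, CPG)] == [4]

    def test_site_outside_window_motif_straddling_kept_if_assayed_c_inside(self):
        # CCAGG starting at 3: assayed C at 4 inside window [4, 9)
        region = _region("AAACCAGGA", window=(4, 9))
        sites = scan_motifs(region, CCWGG)
        assert [s.position for s in sites] == [4]

    @pytest.mark.parametrize("seed", range(10))
    def test_cg_scan_matches_exhaustive_dinucleotide_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        positions = [s.position for s in scan_motifs(_region(seq), CPG)]
        assert positions == helpers.dinucleotide_cg_positions(seq)

    @pytest.mark.parametrize("seed", range(10))
    def test_ccwgg_scan_matches_exhaustive_pentamer_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        positions = [s.position for s in scan_motifs(_region(seq), CCWGG)]
        assert positions == helpers.ccwgg_internal_c_positions(seq)

    def test_ccwgg_family_is_strand_symmetric(self):
        # CCAGG/CCTGG are mutual reverse complements, so the motif count is
        # identical on both strands of any sequence
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            region = _region(seq)
            assert len(scan_motifs(region, CCWGG)) == len(scan_motifs(region, CCWGG, strand="-"))

    def test_fixture_composition(self, region, sites):
        assert sum(s.context == "CpG" for s in sites) == 6
        assert sum(s.context == "CCWGG" for s in sites) == 5

    def test_proximal_pair_is_two_ccwgg_sites_nearest_tss(self, region, sites):
        ccwgg = sorted(
            (s for s in sites if s.context == "CCWGG"),
            key=lambda s: abs(s.position - region.tss_index),
        )
        expected = {s.position for s in ccwgg[:2]}
        assert {s.position for s in sites if s.proximal_pair_member} == expected

    def test_bad_motif_pattern_rejected(self):
        with pytest.raises(ConfigurationError):
            MotifSpec("bad", "CQG", 0)
        with pytest.raises(ConfigurationError):
            MotifSpec("bad", "AG", 0)  # assayed base not C


class TestConvertInsilico:
    def test_full_conversion(self):
        assert convert_insilico("ACGT") == "ATGT"

    def test_protected_c(self):
        assert convert_insilico("ACGT", {1}) == "ACGT"

    def test_non_c_methylated_position_rejected(self):
        with pytest.raises(ValueError):
            convert_insilico("ACGT", {0})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        methylated = set(helpers.dinucleotide_cg_positions(seq))
        converted = convert_insilico(seq, methylated)
        assert converted == helpers.convert_per_base(seq, methylated)
        assert {i for i, b in enumerate(converted) if b == "C"} == methylated

    def test_all_c_methylated_is_identity(self):
        seq = "CCAGGTCGAC"
        all_c = {i for i, b in enumerate(seq) if b == "C"}
        assert convert_insilico(seq, all_c) == seq


class TestAlignmentReference:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "AYGT"), ("CCAGG", "YYAGG")])
    def test_c_to_y(self, seq, expected):
        assert alignment_reference(seq) == expected

    def test_y_count_equals_c_count(self, region):
        assert alignment_reference(region).count("Y") == region.sequence.count("C")


class TestTssLabel:
    def test_promoter_convention(self):
        region = _region("A" * 444, tss=393)
        assert tss_label(region, 393) == 1
        assert tss_label(region, 392) == -1
        assert tss_label(region, 0) == -393
        assert tss_label(region, 443) == 51

    def test_label_zero_never_returned_and_bijective(self, region):
        labels = [tss_label(region, p) for p in range(*region.window)]
        assert 0 not in labels
        assert len(set(labels)) == len(labels)
        for p in range(*region.window):
            assert position_from_tss_label(region, tss_label(region, p)) == p


class TestRegionInvariants:
    def test_snp_allele_c_rejected(self):
        with pytest.raises(ConfigurationError):
            SnpSpec(5, "C", "T")

    def test_identical_alleles_rejected(self):
        with pytest.raises(ConfigurationError):
            SnpSpec(5, "G", "G")

    def test_tss_outside_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            _region("ACGT", tss=4)

    def test_window_outside_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            _region("ACGT", window=(0, 5))

    def test_snp_reference_base_must_match_an_allele(self):
        with pytest.raises(ConfigurationError):
            _region("AAGT", snp=SnpSpec(0, "G", "T"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_conversion_removes_every_unprotected_c(self, seq):
        assert "C" not in convert_insilico(seq)
        assert len(convert_insilico(seq)) == len(seq)
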