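"""Epiallele classification and sample-level promoter methylation state.

A clone's epiallele class summarises its site calls:

* ``unmethylated``        -- no methylated CpG, no methylated CCWGG
* ``cg_only_methylated``  -- CpG fraction >= ``full_threshold``, no CCWGG
* ``cg_ccwgg_methylated`` -- CpG fraction >= ``full_threshold`` plus >= 1
                             methylated CCWGG site
* ``partial``             -- anything in between

The full-methylation threshold defaults to 0.9 rather than 1.0 so one
ambiguous or discordant site does not demote an otherwise fully
methylated clone. A separate flag records whether both designated
proximal (CCWGG)2 sites are methylated.

The sample-level promoter state integrates genotype, allele phasing and
clone classes into one of five labels (see
:func:`classify_promoter_state`). States are pattern labels only; they
carry no claim about the imprinting mechanism behind them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import fisher_exact

from .pipeline import CloneReport

__all__ = [
    "EpialleleClass",
    "SampleProfile",
    "classify_clone",
    "call_genotype",
    "classify_promoter_state",
    "allele_methylation_association",
    "build_profile",
]

FULL_THRESHOLD = 0.9
MIN_CLONES_FOR_STATE = 6

_METHYLATED_CLASSES = ("cg_only_methylated", "cg_ccwgg_methylated")


@dataclass(frozen=True)
class EpialleleClass:
    value: str  # unmethylated | cg_only_methylated | cg_ccwgg_methylated | partial | indeterminate
    proximal_pair_methylated: bool = False
    methylated_cpg_fraction: Optional[float] = None
    n_methylated_cpg: int = 0
    n_methylated_ccwgg: int = 0


@dataclass
class SampleProfile:
    sample: str
    genotype: str  # hom_ref | hom_alt | het | undetermined
    genotype_alleles: tuple[str, ...]
    clone_counts: dict[tuple[str, str], int]  # (allele, class) -> count
    promoter_state: str
    association_p: Optional[float] = None
    n_passed: int = 0
    n_omitted: int = 0

    def counts_by_class(self) -> Counter:
        agg: Counter = Counter()
        for (_, cls), n in self.clone_counts.items():
            agg[cls] += n
        return agg


def classify_clone(report: CloneReport, full_threshold: float = FULL_THRESHOLD) -> EpialleleClass:
    """Assign the clone's epiallele class from its site calls.

    Ambiguous calls are excluded from the CpG fraction; a clone whose CpG
    calls are all ambiguous is indeterminate and is excluded from counts.
    """
    cpg = [c for c in report.site_calls if c.site.context == "CpG" and c.state != "ambiguous"]
    ccwgg_meth = [
        c for c in report.site_calls if c.site.context != "CpG" and c.state == "methylated"
    ]
    proximal = [c for c in report.site_calls if c.site.proximal_pair_member]
    pair_methylated = bool(proximal) and all(c.state == "methylated" for c in proximal)
    if not cpg:
        return EpialleleClass("indeterminate", pair_methylated, None, 0, len(ccwgg_meth))
    n_meth = sum(1 for c in cpg if c.state == "methylated")
    f = n_meth / len(cpg)
    if f == 0 and not ccwgg_meth:
        value = "unmethylated"
    elif f >= full_threshold and not ccwgg_meth:
        value = "cg_only_methylated"
    elif f >= full_threshold:
        value = "cg_ccwgg_methylated"
    else:
        value = "partial"
    return EpialleleClass(value, pair_methylated, f, n_meth, len(ccwgg_meth))


def call_genotype(
    reports: Sequence[CloneReport],
    alleles: tuple[str, str],
    min_minor_clones: int = 2,
    min_minor_fraction: float = 0.10,
) -> tuple[str, tuple[str, ...]]:
    """Genotype from phased clone counts.

    Heterozygous when both alleles are supported by at least
    ``min_minor_clones`` clones and the minor allele reaches
    ``min_minor_fraction`` of determined clones; a thinner minority is
    treated as sequencing error or contamination and the call is
    homozygous for the majority allele.
    """
    counts = Counter(r.allele for r in reports if r.allele in alleles)
    total = sum(counts.values())
    if total == 0:
        return "undetermined", ()
    ref, alt = alleles
    minor_allele, minor = min(counts.items(), key=lambda kv: (kv[1], kv[0])) if len(counts) == 2 else (None, 0)
    if len(counts) == 2 and minor >= min_minor_clones and minor / total >= min_minor_fraction:
        return "het", (ref, alt)
    major = counts.most_common(1)[0][0]
    return ("hom_ref", (ref,)) if major == ref else ("hom_alt", (alt,))


def allele_methylation_association(
    table: Sequence[Sequence[int]],
) -> Optional[float]:
    """Two-sided Fisher exact p for a 2x2 allele x {methylated, unmethylated}
    clone-count table; None when a margin is empty (test undefined)."""
    (a, b), (c, d) = table
    if min(a + b, c + d, a + c, b + d) == 0:
        return None
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def classify_promoter_state(
    genotype: str,
    classified: Sequence[tuple[str, EpialleleClass]],
    discordance_allowance: int = 1,
    min_clones: int = MIN_CLONES_FOR_STATE,
) -> str:
    """Sample-level promoter methylation state from (allele, class) pairs.

    Rules, evaluated in order on QC-passed, determinate clones:

    1. *SNP-phased monoallelic*: heterozygous; >= 2 unmethylated clones all
       on one allele and >= 2 signature-methylated clones (CG+CCWGG when
       any exist, otherwise CG-only) all on the other, tolerating at most
       ``discordance_allowance`` clones on the wrong side. CG-only or
       partial clones sharing the unmethylated allele are not counted as
       discordant: a monoallelically methylated promoter may carry minor
       CG-only epialleles on the silent allele.
    2. *Biallelic methylated*: >= 90% of clones fully methylated.
    3. *Biallelic unmethylated*: no fully methylated clone, at most 25% of
       clones with any methylated call and at most one clone with two or
       more methylated CpGs (tolerates stray conversion failures).
    4. *Pattern-based monoallelic* (phasing-free fallback, required for
       homozygous samples): the bimodal all-or-none split -- both modes
       well represented (30-70% fully methylated clones, >= 25%
       unmethylated clones) with at most 20% partial clones.
    5. *Stochastic biallelic*: every clone carries >= 1 methylated CpG but
       the per-clone patterns are heterogeneous.

    Anything else, or fewer than ``min_clones`` clones, is indeterminate.
    """
    clones = [(a, c) for a, c in classified if c.value != "indeterminate"]
    if len(clones) < min_clones:
        return "indeterminate"
    n = len(clones)
    values = [c.value for _, c in clones]
    m = sum(1 for v in values if v in _METHYLATED_CLASSES) / n
    partial_fraction = values.count("partial") / n

    if genotype == "het":
        unmeth_alleles = Counter(a for a, c in clones if c.value == "unmethylated")
        signature = "cg_ccwgg_methylated" if "cg_ccwgg_methylated" in values else "cg_only_methylated"
        sig_alleles = Counter(a for a, c in clones if c.value == signature)
        if sum(unmeth_alleles.values()) >= 2 and sum(sig_alleles.values()) >= 2:
            unmeth_major = unmeth_alleles.most_common(1)[0][0]
            sig_major = sig_alleles.most_common(1)[0][0]
            if unmeth_major != sig_major and unmeth_major != "undetermined" and sig_major != "undetermined":
                discordant = (
                    sum(v for a, v in unmeth_alleles.items() if a == sig_major)
                    + sum(v for a, v in sig_alleles.items() if a == unmeth_major)
                )
                if discordant <= discordance_allowance:
                    return "monoallelic_methylation"

    if m >= 0.90:
        return "biallelic_methylated"

    any_meth = [c.n_methylated_cpg > 0 or c.n_methylated_ccwgg > 0 for _, c in clones]
    multi_cpg = sum(1 for _, c in clones if c.n_methylated_cpg >= 2)
    if m == 0 and sum(any_meth) / n <= 0.25 and multi_cpg <= 1:
        return "biallelic_unmethylated"

    unmeth_fraction = values.count("unmethylated") / n
    if 0.30 <= m <= 0.70 and unmeth_fraction >= 0.25 and partial_fraction <= 0.20:
        return "monoallelic_methylation"

    if all(any_meth):
        patterns = {
            (round(c.methylated_cpg_fraction or 0, 6), c.n_methylated_ccwgg) for _, c in clones
        }
        if len(patterns) >= 2 or partial_fraction > 0:
            return "stochastic_biallelic"

    return "indeterminate"


def build_profile(
    sample: str,
    passed: Sequence[CloneReport],
    omitted: Sequence[CloneReport],
    alleles: tuple[str, str],
    full_threshold: float = FULL_THRESHOLD,
) -> SampleProfile:
    """Aggregate QC-passed clone reports into the sample profile."""
    genotype, genotype_alleles = call_genotype(passed, alleles)
    classified = [(r.allele, classify_clone(r, full_threshold)) for r in passed]
    counts: dict[tuple[str, str], int] = {}
    for allele, cls in classified:
        if cls.value == "indeterminate":
            continue
        key = (allele, cls.value)
        counts[key] = counts.get(key, 0) + 1
    state = classify_promoter_state(genotype, classified)
    association_p = None
    if genotype == "het":
        ref, alt = alleles
        def cell(allele: str, methylated: bool) -> int:
            classes = _METHYLATED_CLASSES if methylated else ("unmethylated",)
            return sum(v for (a, c), v in counts.items() if a == allele and c in classes)
        table = [[cell(ref, True), cell(ref, False)], [cell(alt, True), cell(alt, False)]]
        association_p = allele_methylation_association(table)
    return SampleProfile(
        sample=sample,
        genotype=genotype,
        genotype_alleles=genotype_alleles,
        clone_counts=counts,
        promoter_state=state,
        association_p=association_p,
        n_passed=len(passed),
        n_omitted=len(omitted),
    )
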