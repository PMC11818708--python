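"""Per-clone bisulfite pipeline: align, call sites, QC, phase.

Each clone is globally aligned once against the all-Y reference (Y scores
as a match to both C and T), so the alignment itself is neutral to
methylation state; methylation, conversion efficiency and the phasing SNP
are then read off the reference-coordinate map.

Conversion efficiency is the fraction of *non-assayed* reference cytosines
(outside every configured methylation context, CpG and CCWGG alike) that
read as T. Cytosines in assayed contexts may be genuinely methylated and
would bias the statistic, so they are excluded from the denominator by
default. Clones converting fewer than 98% of eligible cytosines are
omitted (strict less-than), as are clones covering less than 90% of the
analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .reference import MethylSite, ReferenceRegion, alignment_reference

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP_OPEN",
    "GAP_EXTEND",
    "SiteCall",
    "CloneReport",
    "align_clone",
    "call_sites",
    "conversion_efficiency",
    "assign_allele",
    "qc_filter",
    "process_clone",
    "process_clones",
]

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -5.0  # cost of the first gap column
GAP_EXTEND = -2.0  # cost of each further gap column

QC_THRESHOLD = 0.98
MIN_WINDOW_COVERAGE = 0.90

_ALPHABET = "ACGTYN"


def _substitution_matrix(bisulfite: bool) -> substitution_matrices.Array:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if "N" in (a, b):
                m[a, b] = -1.0  # N neither rewarded nor punished like a mismatch
            else:
                m[a, b] = MATCH if a == b else MISMATCH
    if bisulfite:
        # the degenerate reference pyrimidine accepts either read state
        for b in "CT":
            m["Y", b] = MATCH
            m[b, "Y"] = MATCH
    return m


@lru_cache(maxsize=4)
def _aligner(bisulfite: bool = True) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(bisulfite)
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _sanitise(read: str) -> str:
    read = read.upper().replace("U", "T")
    return "".join(b if b in "ACGTN" else "N" for b in read)


@dataclass(frozen=True)
class CloneAlignment:
    """Global alignment of one clone, as a reference-coordinate base map."""

    clone_id: str
    ref_map: tuple[Optional[str], ...]  # index = reference position; None = gap
    score: float

    def base_at(self, position: int) -> Optional[str]:
        return self.ref_map[position]

    def window_coverage(self, window: tuple[int, int]) -> float:
        start, end = window
        covered = sum(1 for b in self.ref_map[start:end] if b is not None)
        return covered / (end - start)


@dataclass(frozen=True)
class SiteCall:
    site: MethylSite
    state: str  # methylated | unmethylated | ambiguous
    observed_base: Optional[str]


@dataclass
class CloneReport:
    clone_id: str
    site_calls: list[SiteCall]
    conversion_efficiency: Optional[float]
    n_converted_c: int
    n_eligible_c: int
    passes_qc: bool
    allele: str  # one of the SNP alleles or "undetermined"
    omit_reason: Optional[str] = None
    window_coverage: float = 1.0

    def methylated_cpg(self) -> int:
        return sum(
            1 for c in self.site_calls if c.site.context == "CpG" and c.state == "methylated"
        )


def align_clone(
    read: str, region: ReferenceRegion, clone_id: str = "clone", bisulfite: bool = True
) -> CloneAlignment:
    """Global alignment of ``read`` against the (Y-degenerate) reference.

    Scoring: match +2, mismatch -3, gap open -5, gap extend -2; a gap of
    length L costs 5 + 2(L-1). For bisulfite reads the reference is the
    all-Y template from :func:`~allelobis.reference.alignment_reference`;
    for unconverted (cDNA) reads pass ``bisulfite=False``.
    """
    if not read:
        raise ValueError("empty read")
    target = alignment_reference(region) if bisulfite else region.sequence
    query = _sanitise(read)
    alignments = _aligner(bisulfite).align(target, query)
    best = alignments[0]
    ref_map: list[Optional[str]] = [None] * len(target)
    for (t_start, t_end), (q_start, q_end) in zip(*best.aligned):
        for offset in range(t_end - t_start):
            ref_map[t_start + offset] = query[q_start + offset]
    return CloneAlignment(clone_id=clone_id, ref_map=tuple(ref_map), score=best.score)


def call_sites(alignment: CloneAlignment, sites: Sequence[MethylSite]) -> list[SiteCall]:
    """One call per assayed site: C = methylated, T = unmethylated,
    anything else (gap, N, other base) = ambiguous."""
    calls = []
    for site in sites:
        base = alignment.base_at(site.position)
        if base == "C":
            state = "methylated"
        elif base == "T":
            state = "unmethylated"
        else:
            state = "ambiguous"
        calls.append(SiteCall(site=site, state=state, observed_base=base))
    return calls


def conversion_efficiency(
    alignment: CloneAlignment,
    region: ReferenceRegion,
    exclude_assayed_contexts: bool = True,
) -> tuple[Optional[float], int, int]:
    """(efficiency, n_converted, n_eligible) for one aligned clone.

    Eligible positions are reference Cs inside the window outside every
    assayed context (set ``exclude_assayed_contexts=False`` to exclude
    only CpG Cs). Positions reading neither C nor T (gap, N, substitution)
    are dropped from both counts. Efficiency is None when nothing is
    eligible.
    """
    assayed = region.assayed_positions() if exclude_assayed_contexts else {
        s.position for s in region.sites() if s.context == "CpG"
    }
    start, end = region.window
    n_eligible = 0
    n_converted = 0
    for pos in range(start, end):
        if region.sequence[pos] != "C" or pos in assayed:
            continue
        base = alignment.base_at(pos)
        if base == "T":
            n_eligible += 1
            n_converted += 1
        elif base == "C":
            n_eligible += 1
    if n_eligible == 0:
        return None, 0, 0
    return n_converted / n_eligible, n_converted, n_eligible


def assign_allele(alignment: CloneAlignment, region: ReferenceRegion) -> str:
    """Phase the clone via the SNP: exact allele match or 'undetermined'."""
    if region.snp is None:
        raise ValueError("region has no SNP configured; phasing unavailable")
    base = alignment.base_at(region.snp.position)
    if base in region.snp.alleles:
        return base
    return "undetermined"


def qc_filter(
    reports: Sequence[CloneReport], threshold: float = QC_THRESHOLD
) -> tuple[list[CloneReport], list[CloneReport]]:
    """Partition reports into (passed, omitted) at ``threshold``.

    Strict rule: efficiency < threshold is omitted, efficiency == threshold
    passes; undefined efficiency is omitted with its own reason code.
    Reports already carrying an omit reason (e.g. truncated) stay omitted.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    passed, omitted = [], []
    for report in reports:
        if report.omit_reason == "truncated":
            omitted.append(report)
            continue
        if report.conversion_efficiency is None:
            report.passes_qc = False
            report.omit_reason = "no_eligible_cytosines"
            omitted.append(report)
        elif report.conversion_efficiency < threshold:
            report.passes_qc = False
            report.omit_reason = "low_conversion"
            omitted.append(report)
        else:
            report.passes_qc = True
            report.omit_reason = None
            passed.append(report)
    return passed, omitted


def process_clone(
    clone_id: str,
    read: str,
    region: ReferenceRegion,
    qc_threshold: float = QC_THRESHOLD,
    min_coverage: float = MIN_WINDOW_COVERAGE,
) -> CloneReport:
    """Align one clone and assemble its full report (QC verdict included)."""
    alignment = align_clone(read, region, clone_id=clone_id)
    coverage = alignment.window_coverage(region.window)
    calls = call_sites(alignment, region.sites())
    efficiency, n_conv, n_elig = conversion_efficiency(alignment, region)
    allele = assign_allele(alignment, region) if region.snp is not None else "undetermined"
    report = CloneReport(
        clone_id=clone_id,
        site_calls=calls,
        conversion_efficiency=efficiency,
        n_converted_c=n_conv,
        n_eligible_c=n_elig,
        passes_qc=False,
        allele=allele,
        window_coverage=coverage,
    )
    if coverage < min_coverage:
        report.omit_reason = "truncated"
        return report
    report.passes_qc = (
        efficiency is not None and efficiency >= qc_threshold
    )
    if efficiency is None:
        report.omit_reason = "no_eligible_cytosines"
    elif not report.passes_qc:
        report.omit_reason = "low_conversion"
    return report


def process_clones(
    reads: Sequence[tuple[str, str]],
    region: ReferenceRegion,
    qc_threshold: float = QC_THRESHOLD,
    min_coverage: float = MIN_WINDOW_COVERAGE,
) -> tuple[list[CloneReport], list[CloneReport]]:
    """Run the per-clone pipeline over a clone set; returns (passed, omitted)."""
    reports = [
        process_clone(clone_id, read, region, qc_threshold, min_coverage)
        for clone_id, read in reads
    ]
    return qc_filter(reports, qc_threshold)
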