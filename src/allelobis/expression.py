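"""Allelic expression from cDNA clones and relative expression by 2^-ddCt.

A transcribed SNP lets cDNA clone sequencing read out which allele each
transcript came from: a roughly even split is biallelic expression, a
strong skew suggests monoallelic expression. cDNA is unconverted, so
clones are aligned against the plain transcript reference (no Y
degeneracy) with the same global aligner as the bisulfite pipeline.

Relative expression follows the Livak 2^-ddCt method: Ct values of the
target gene are normalised to a reference gene (here typically TBP)
within each sample (dCt), then to a calibrator sample (ddCt);
rq = 2^-ddCt. Replicates are aggregated by arithmetic mean of Ct and the
dCt standard deviation is propagated as the root sum of squares of the
replicate SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binomtest

__all__ = [
    "TranscribedSNP",
    "AllelicExpressionResult",
    "CtRecord",
    "RelativeExpression",
    "count_allelic_clones",
    "imbalance_test",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class TranscribedSNP:
    name: str
    position: int  # 0-based index within the transcript reference
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = (x.upper() for x in self.alleles)
        if a == b:
            raise ValueError("SNP alleles must be distinct")
        object.__setattr__(self, "alleles", (a, b))


@dataclass
class AllelicExpressionResult:
    snp: TranscribedSNP
    counts: dict[str, int]
    n_undetermined: int
    binomial_p: Optional[float] = None
    verdict: str = "indeterminate"

    @property
    def n_determined(self) -> int:
        return sum(self.counts.values())


def count_allelic_clones(
    reads: Sequence[tuple[str, str]],
    transcript: str,
    snp: TranscribedSNP,
) -> AllelicExpressionResult:
    """Tally cDNA clones by the base observed at the transcribed SNP.

    Each read is globally aligned to the transcript reference; the aligned
    base at ``snp.position`` is compared with the two alleles, anything
    else (gap, N, third base) counts as undetermined.
    """
    from .pipeline import align_clone  # deferred: pipeline imports reference only
    from .reference import ReferenceRegion

    region = ReferenceRegion(
        name="transcript", sequence=transcript, tss_index=0, window=(0, len(transcript))
    )
    counts = {a: 0 for a in snp.alleles}
    undetermined = 0
    for clone_id, read in reads:
        alignment = align_clone(read, region, clone_id=clone_id, bisulfite=False)
        base = alignment.base_at(snp.position)
        if base in counts:
            counts[base] += 1
        else:
            undetermined += 1
    result = AllelicExpressionResult(snp=snp, counts=counts, n_undetermined=undetermined)
    if result.n_determined == 0:
        result.verdict = "no_coverage"
        return result
    result.binomial_p, result.verdict = imbalance_test(counts)
    return result


def imbalance_test(counts: dict[str, int], min_total: int = 10) -> tuple[Optional[float], str]:
    """Exact two-sided binomial test of allelic balance against 0.5.

    Verdicts: ``biallelic`` when p >= 0.05 and the minor allele carries at
    least 20% of determined clones; ``monoallelic_skewed`` when the minor
    allele falls below 5%; otherwise ``indeterminate``. Fewer than
    ``min_total`` determined clones is always indeterminate.
    """
    values = sorted(counts.values())
    total = sum(values)
    if total < min_total:
        return None, "indeterminate"
    minor = values[0]
    p = float(binomtest(minor, total, 0.5, alternative="two-sided").pvalue)
    minor_fraction = minor / total
    if minor_fraction < 0.05:
        return p, "monoallelic_skewed"
    if p >= 0.05 and minor_fraction >= 0.2:
        return p, "biallelic"
    return p, "indeterminate"


@dataclass(frozen=True)
class CtRecord:
    """qPCR threshold cycles for one (sample, gene) pair."""

    sample: str
    gene: str
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cts:
            raise ValueError(f"no Ct replicates for {self.sample}/{self.gene}")
        if any(ct <= 0 for ct in self.cts):
            raise ValueError("Ct values must be positive")
        object.__setattr__(self, "cts", tuple(float(c) for c in self.cts))

    @property
    def mean(self) -> float:
        return float(np.mean(self.cts))

    @property
    def sd(self) -> float:
        return float(np.std(self.cts, ddof=1)) if len(self.cts) > 1 else 0.0


@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    gene: str
    calibrator: str
    delta_ct: float
    delta_ct_calibrator: float
    delta_delta_ct: float
    rq: float
    sd_delta_ct: float
    rq_low: float
    rq_high: float


def delta_delta_ct(
    target: CtRecord,
    reference: CtRecord,
    calibrator_target: CtRecord,
    calibrator_reference: CtRecord,
) -> RelativeExpression:
    """Livak relative quantification: rq = 2^-ddCt.

    dCt = mean Ct(target) - mean Ct(reference gene) per sample;
    ddCt = dCt(sample) - dCt(calibrator). The dCt SD is the root sum of
    squares of the target and reference replicate SDs and is propagated
    to an rq range [2^-(ddCt+sd), 2^-(ddCt-sd)].
    """
    if target.sample != reference.sample:
        raise ValueError("target and reference Ct records are from different samples")
    if calibrator_target.sample != calibrator_reference.sample:
        raise ValueError("calibrator Ct records are from different samples")
    d_ct = target.mean - reference.mean
    d_ct_cal = calibrator_target.mean - calibrator_reference.mean
    dd_ct = d_ct - d_ct_cal
    sd = math.sqrt(target.sd**2 + reference.sd**2)
    rq = 2.0 ** (-dd_ct)
    return RelativeExpression(
        sample=target.sample,
        gene=target.gene,
        calibrator=calibrator_target.sample,
        delta_ct=d_ct,
        delta_ct_calibrator=d_ct_cal,
        delta_delta_ct=dd_ct,
        rq=rq,
        sd_delta_ct=sd,
        rq_low=2.0 ** (-(dd_ct + sd)),
        rq_high=2.0 ** (-(dd_ct - sd)),
    )
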