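"""Bundled synthetic benchmark datasets with known truth.

Each dataset emulates the clone composition characteristic of a
well-studied prostate (or control) cell line at the PSA-like promoter:

* ``BPH1``      -- heterozygous A/G; 8 unmethylated clones on the A allele,
                   5 fully CG+CCWGG-methylated clones on the G allele and
                   3 CG-only-methylated clones on the A allele (16 clones);
                   the monoallelic-methylation archetype.
* ``HPrEpiC``   -- heterozygous A/G; 16 clones, every clone carrying at
                   least one methylated CpG in a stochastic per-clone
                   pattern, no CCWGG methylation; stochastic biallelic.
* ``LNCaP``     -- homozygous A/A; 20 fully unmethylated clones.
* ``PC3``       -- homozygous A/A; 20 fully CpG-methylated clones, exactly
                   one additionally methylated at the proximal (CCWGG)2.
* ``PA1``       -- homozygous A/A; 10 unmethylated + 10 fully
                   CG+(CCWGG)2-methylated clones (monoallelic pattern that
                   cannot be SNP-phased).
* ``LNCaP_cDNA`` -- 20 unconverted transcript clones, 10 carrying G and
                   10 carrying A at the transcribed exon-3 SNP.

All sequences are generated deterministically from a seed; the returned
truth table records allele, pattern label and per-site states so the whole
pipeline can be validated by round trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .expression import TranscribedSNP
from .reference import ReferenceRegion
from .simulate import ClonePattern, SimulationConfig, make_reference, simulate_clone_set

__all__ = [
    "GDNA_SAMPLES",
    "SAMPLE_NAMES",
    "CloneDataset",
    "promoter_region",
    "transcript_reference",
    "load_sample",
]

GDNA_SAMPLES = ("HPrEpiC", "BPH1", "LNCaP", "PC3", "PA1")
SAMPLE_NAMES = GDNA_SAMPLES + ("LNCaP_cDNA",)

#: region-generation seed; fixed so the bundled reference is stable
_REGION_SEED = 20_240_131


@dataclass(frozen=True)
class CloneDataset:
    """Clone reads plus ground truth for one benchmark sample."""

    sample: str
    reads: list[tuple[str, str]]  # (clone_id, sequence)
    truth: pd.DataFrame  # clone_id, allele, label, site_<pos> columns
    region: Optional[ReferenceRegion] = None
    snp: Optional[TranscribedSNP] = None
    transcript: Optional[str] = None


def promoter_region() -> ReferenceRegion:
    """The bundled 444-nt promoter-like reference: window -393..+51,
    6 CpG + 5 CCWGG sites, heterozygosity-capable G/A SNP at -158."""
    return make_reference(seed=_REGION_SEED, n_cpg=6, n_ccwgg=5, window_length=444)


def transcript_reference(length: int = 700, snp_position: int = 446) -> tuple[str, TranscribedSNP]:
    """A synthetic transcript with a G/A polymorphism at exon-3-like nt 447
    (0-based index 446)."""
    rng = np.random.default_rng(_REGION_SEED + 1)
    seq = rng.choice(list("ACGT"), size=length)
    seq[snp_position] = "G"
    return "".join(seq), TranscribedSNP("exon3_nt447_G/A", snp_position, ("G", "A"))


def _uniform_pattern(region: ReferenceRegion, allele: str, label: str, *,
                     cpg: bool, ccwgg: bool, proximal_only: bool = False) -> ClonePattern:
    states = {}
    for site in region.sites():
        if site.context == "CpG":
            states[site.position] = cpg
        elif proximal_only:
            states[site.position] = ccwgg and site.proximal_pair_member
        else:
            states[site.position] = ccwgg
    return ClonePattern(allele=allele, site_states=states, label=label)


def _stochastic_patterns(region: ReferenceRegion, n: int, alleles: list[str],
                         seed: int) -> list[ClonePattern]:
    """Per-clone stochastic CpG patterns: 1..(n_cpg-2) methylated CpGs per
    clone, never all and never none, no CCWGG methylation, patterns
    guaranteed heterogeneous across the set."""
    rng = np.random.default_rng(seed)
    cpg = [s.position for s in region.sites() if s.context == "CpG"]
    other = [s.position for s in region.sites() if s.context != "CpG"]
    patterns: list[ClonePattern] = []
    seen: set[frozenset] = set()
    for i in range(n):
        for _ in range(100):
            k = int(rng.integers(1, max(2, len(cpg) - 1)))
            chosen = frozenset(rng.choice(cpg, size=k, replace=False).tolist())
            if chosen not in seen or len(seen) >= 2 ** len(cpg) - 2:
                break
        seen.add(chosen)
        states = {p: (p in chosen) for p in cpg}
        states.update({p: False for p in other})
        patterns.append(ClonePattern(allele=alleles[i % len(alleles)],
                                     site_states=states, label="stochastic"))
    return patterns


def _gdna_patterns(sample: str, region: ReferenceRegion, seed: int) -> list[ClonePattern]:
    A, G = "A", "G"
    unmeth = lambda a: _uniform_pattern(region, a, "unmethylated", cpg=False, ccwgg=False)
    cg_only = lambda a: _uniform_pattern(region, a, "CG_only", cpg=True, ccwgg=False)
    full = lambda a: _uniform_pattern(region, a, "full_CG_CCWGG", cpg=True, ccwgg=True)
    full_prox = lambda a: _uniform_pattern(region, a, "full_CG_CCWGG2", cpg=True,
                                           ccwgg=True, proximal_only=True)
    if sample == "BPH1":
        return [unmeth(A)] * 8 + [full(G)] * 5 + [cg_only(A)] * 3
    if sample == "HPrEpiC":
        return _stochastic_patterns(region, 16, [A, G], seed)
    if sample == "LNCaP":
        return [unmeth(A)] * 20
    if sample == "PC3":
        return [full_prox(A)] + [cg_only(A)] * 19
    if sample == "PA1":
        return [unmeth(A)] * 10 + [full_prox(A)] * 10
    raise KeyError(f"unknown sample {sample!r}; expected one of {SAMPLE_NAMES}")


def _truth_table(region: ReferenceRegion, patterns: list[ClonePattern],
                 reads: list[tuple[str, str]]) -> pd.DataFrame:
    site_positions = [s.position for s in region.sites()]
    rows = []
    for (clone_id, _), pattern in zip(reads, patterns):
        row = {"clone_id": clone_id, "allele": pattern.allele, "label": pattern.label}
        for pos in site_positions:
            row[f"site_{pos}"] = "M" if pattern.site_states[pos] else "U"
        rows.append(row)
    return pd.DataFrame(rows)


def load_sample(
    sample: str,
    seed: int = 0,
    conversion_failure_rate: float = 0.0,
    sequencing_error_rate: float = 0.0,
) -> CloneDataset:
    """Generate one benchmark dataset.

    ``seed`` controls the noise process and the stochastic per-clone CpG
    patterns; the reference region and the clone-composition tables are
    fixed. At the default zero noise rates the reads encode the truth
    table exactly.
    """
    if sample == "LNCaP_cDNA":
        transcript, snp = transcript_reference()
        reads = []
        rows = []
        for i in range(20):
            allele = "G" if i < 10 else "A"
            seq = transcript[: snp.position] + allele + transcript[snp.position + 1 :]
            clone_id = f"cdna_{i + 1:03d}_{allele}"
            reads.append((clone_id, seq))
            rows.append({"clone_id": clone_id, "allele": allele, "label": "transcript"})
        return CloneDataset(sample=sample, reads=reads, truth=pd.DataFrame(rows),
                            snp=snp, transcript=transcript)

    region = promoter_region()
    patterns = _gdna_patterns(sample, region, seed=seed + 7)
    cfg = SimulationConfig(
        conversion_failure_rate=conversion_failure_rate,
        sequencing_error_rate=sequencing_error_rate,
        seed=seed,
    )
    reads = simulate_clone_set(region, patterns, cfg)
    return CloneDataset(sample=sample, reads=reads,
                        truth=_truth_table(region, patterns, reads), region=region)
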