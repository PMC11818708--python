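"""Synthetic promoter regions and bisulfite clone reads with known ground truth.

The generator plants an exact number of CpG and CCWGG occurrences (and
nothing else that scans as either motif) into a C-free backbone, plus a
pool of isolated non-motif cytosines that serve as conversion-efficiency
sentinels, then verifies its own composition with the motif scanner.

Clone simulation follows the chemistry: methylated cytosines resist
conversion and read as C; unmethylated cytosines convert to T except with
probability ``conversion_failure_rate`` (incomplete bisulfite treatment);
uniform substitution errors model Sanger read noise. Conversion failure
never creates a C from a non-C base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .reference import (
    CCWGG,
    CPG,
    MethylSite,
    ReferenceRegion,
    SnpSpec,
    convert_insilico,
    position_from_tss_label,
    scan_motifs,
)

__all__ = [
    "ClonePattern",
    "SimulationConfig",
    "GenerationError",
    "make_reference",
    "simulate_clone",
    "simulate_clone_set",
    "random_pattern",
]


class GenerationError(RuntimeError):
    """Requested region composition could not be realised."""


@dataclass(frozen=True)
class ClonePattern:
    """Ground-truth epiallele: one allele plus a per-site methylation map.

    ``site_states`` maps assayed-C position -> True (methylated).
    It must cover exactly the region's assayable sites.
    """

    allele: str
    site_states: Mapping[int, bool]
    label: str = ""

    def methylated_positions(self) -> set[int]:
        return {pos for pos, state in self.site_states.items() if state}


@dataclass(frozen=True)
class SimulationConfig:
    conversion_failure_rate: float = 0.0
    sequencing_error_rate: float = 0.0
    seed: int = 0
    n_clones_per_pattern: int = 1

    def __post_init__(self) -> None:
        for rate in (self.conversion_failure_rate, self.sequencing_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


_BACKBONE = np.array(list("ATG"))


def make_reference(
    seed: int,
    n_cpg: int = 6,
    n_ccwgg: int = 5,
    window_length: int = 444,
    snp_tss_label: Optional[int] = -158,
    snp_alleles: tuple[str, str] = ("G", "A"),
    snp_label: str = "G-158A",
    n_sentinel_c: int = 36,
    tss_downstream: int = 51,
    name: str = "synthetic-promoter",
    max_attempts: int = 50,
) -> ReferenceRegion:
    """Build a promoter-like region with an exact CpG/CCWGG composition.

    The window covers the whole sequence; the TSS sits ``tss_downstream``
    bases from the right edge so the default 444-nt window spans -393..+51
    in promoter coordinates. ``n_sentinel_c`` isolated non-motif Cs are
    planted to give the conversion-efficiency statistic a denominator.
    Deterministic for a fixed seed; the composition is verified by
    scanning before the region is returned.
    """
    rng = np.random.default_rng(seed)
    tss_index = window_length - tss_downstream
    if tss_index < 0:
        raise GenerationError("window shorter than the downstream TSS offset")
    snp_position = None
    if snp_tss_label is not None:
        snp_position = (
            tss_index + snp_tss_label - 1 if snp_tss_label > 0 else tss_index + snp_tss_label
        )
        if not 0 <= snp_position < window_length:
            raise GenerationError("SNP label falls outside the window")

    for _ in range(max_attempts):
        seq = rng.choice(_BACKBONE, size=window_length)
        reserved: set[int] = set()
        if snp_position is not None:
            reserved.update(range(max(0, snp_position - 5), min(window_length, snp_position + 6)))

        def place(length: int, clearance: int = 2) -> Optional[int]:
            # keep >=2 bp clearance between planted elements: every C in the
            # region is planted, so no two Cs can become adjacent and no
            # accidental CC (hence CCWGG) can arise; accidental CG is ruled
            # out by forcing the base after a sentinel C away from G
            candidates = [
                p
                for p in range(1, window_length - length - 1)
                if all((p + o) not in reserved for o in range(-clearance, length + clearance))
            ]
            if not candidates:
                return None
            p = int(rng.choice(candidates))
            reserved.update(range(p - clearance, p + length + clearance))
            return p

        ok = True
        for _ in range(n_ccwgg):
            p = place(5)
            if p is None:
                ok = False
                break
            w = rng.choice(["A", "T"])
            seq[p : p + 5] = list(f"CC{w}GG")
        if ok:
            for _ in range(n_cpg):
                p = place(2)
                if p is None:
                    ok = False
                    break
                seq[p : p + 2] = list("CG")
        if ok:
            planted_c = 0
            for _ in range(n_sentinel_c):
                p = place(1)
                if p is None:
                    break
                # a sentinel C must not be followed by G (would be a CpG)
                if seq[p + 1] == "G":
                    seq[p + 1] = rng.choice(["A", "T"])
                seq[p] = "C"
                planted_c += 1
            if planted_c < n_sentinel_c:
                ok = False
        if not ok:
            continue

        snp = None
        if snp_position is not None:
            seq[snp_position] = snp_alleles[0]
            snp = SnpSpec(snp_position, snp_alleles[0], snp_alleles[1], snp_label)
        region = ReferenceRegion(
            name=name,
            sequence="".join(seq),
            tss_index=tss_index,
            window=(0, window_length),
            snp=snp,
        )
        if len(scan_motifs(region, CPG)) == n_cpg and len(scan_motifs(region, CCWGG)) == n_ccwgg:
            return region
    raise GenerationError(
        f"could not realise {n_cpg} CpG + {n_ccwgg} CCWGG in {window_length} nt "
        f"after {max_attempts} attempts"
    )


def random_pattern(
    region: ReferenceRegion,
    rng: np.random.Generator,
    allele: Optional[str] = None,
    label: str = "random",
) -> ClonePattern:
    """A uniformly random site-state vector over the region's sites."""
    sites = region.sites()
    if allele is None:
        allele = str(rng.choice(region.snp.alleles)) if region.snp else "N"
    states = {s.position: bool(rng.integers(0, 2)) for s in sites}
    return ClonePattern(allele=allele, site_states=states, label=label)


def simulate_clone(
    region: ReferenceRegion,
    pattern: ClonePattern,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """One bisulfite clone read realising ``pattern`` under the noise model."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    seq = list(region.sequence)
    if region.snp is not None:
        if pattern.allele not in region.snp.alleles:
            raise ValueError(f"pattern allele {pattern.allele!r} is not a SNP allele")
        seq[region.snp.position] = pattern.allele
    methylated = pattern.methylated_positions()
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i in methylated:
            continue  # 5mC resists conversion
        if cfg.conversion_failure_rate > 0 and rng.random() < cfg.conversion_failure_rate:
            continue  # incomplete conversion: still reads C
        seq[i] = "T"
    if cfg.sequencing_error_rate > 0:
        for i, base in enumerate(seq):
            if rng.random() < cfg.sequencing_error_rate:
                seq[i] = str(rng.choice([b for b in "ACGT" if b != base]))
    return "".join(seq)


def simulate_clone_set(
    region: ReferenceRegion,
    patterns: Sequence[ClonePattern],
    cfg: SimulationConfig,
) -> list[tuple[str, str]]:
    """(clone_id, sequence) pairs, one clone per pattern repetition.

    A single generator seeded with ``cfg.seed`` drives all clones, so the
    whole set is reproducible as a unit.
    """
    rng = np.random.default_rng(cfg.seed)
    reads = []
    counter = 0
    for pattern in patterns:
        for _ in range(cfg.n_clones_per_pattern):
            counter += 1
            clone_id = f"clone_{counter:03d}_{pattern.label or 'pattern'}"
            reads.append((clone_id, simulate_clone(region, pattern, cfg, rng)))
    return reads
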