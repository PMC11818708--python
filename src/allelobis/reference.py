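"""Reference promoter model: assayable-site discovery and in-silico bisulfite conversion.

The analysis window is anchored on the transcription start site (TSS).
Promoter convention is used throughout: the +1 base is the TSS itself,
upstream positions count -1, -2, ... leftward and there is no position 0.
Internally all coordinates are 0-based half-open offsets into the region
sequence; TSS-relative labels are presentation only.

Two methylation contexts are modelled by default:

* ``CpG`` -- the canonical mammalian context; the assayed cytosine is the C
  of the CG dinucleotide.
* ``CCWGG`` (W = A/T) -- a Dcm-like pentanucleotide context; the assayed
  cytosine is the *internal* (second) C, mirroring C(m)CWGG methylation.
  The assayed offset is configurable because either C could in principle
  carry the mark.

Only the top (amplified) strand is analysed by default: bisulfite PCR
primer sets amplify a single strand, so a clone set reports one strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "MotifSpec",
    "SnpSpec",
    "MethylSite",
    "ReferenceRegion",
    "CPG",
    "CCWGG",
    "DEFAULT_MOTIFS",
    "scan_motifs",
    "convert_insilico",
    "alignment_reference",
    "tss_label",
    "position_from_tss_label",
]

_IUPAC = {code: frozenset(expansion) for code, expansion in ambiguous_dna_values.items()}


class ConfigurationError(ValueError):
    """Raised when a region/motif configuration is internally inconsistent."""


@dataclass(frozen=True)
class MotifSpec:
    """A methylation context defined by an IUPAC pattern.

    ``assayed_offset`` is the 0-based index of the cytosine whose
    methylation state the assay reads out.
    """

    name: str
    pattern: str
    assayed_offset: int

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        object.__setattr__(self, "pattern", pattern)
        for base in pattern:
            if base not in _IUPAC:
                raise ConfigurationError(f"unknown IUPAC code {base!r} in motif {self.name!r}")
        if not 0 <= self.assayed_offset < len(pattern):
            raise ConfigurationError(f"assayed_offset out of range for motif {self.name!r}")
        if pattern[self.assayed_offset] != "C":
            raise ConfigurationError(
                f"assayed position of motif {self.name!r} must be C, got "
                f"{pattern[self.assayed_offset]!r}"
            )

    def matches_at(self, sequence: str, start: int) -> bool:
        """Whether the pattern matches ``sequence`` at offset ``start``."""
        end = start + len(self.pattern)
        if start < 0 or end > len(sequence):
            return False
        return all(sequence[start + j] in _IUPAC[p] for j, p in enumerate(self.pattern))


CPG = MotifSpec("CpG", "CG", 0)
CCWGG = MotifSpec("CCWGG", "CCWGG", 1)
DEFAULT_MOTIFS: tuple[MotifSpec, ...] = (CPG, CCWGG)


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP used to phase clones to parental alleles.

    Neither allele may be C on the analysed strand: a C allele would be
    scrambled by bisulfite conversion and phasing would be impossible.
    """

    position: int
    ref_allele: str
    alt_allele: str
    label: str = ""

    def __post_init__(self) -> None:
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)
        if ref == alt:
            raise ConfigurationError("SNP alleles must be distinct")
        for allele in (ref, alt):
            if allele not in "ACGT":
                raise ConfigurationError(f"SNP allele must be a concrete base, got {allele!r}")
            if allele == "C":
                raise ConfigurationError(
                    "SNP allele C is not phaseable after bisulfite conversion "
                    "(C reads as C or T depending on methylation)"
                )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class MethylSite:
    """One assayable cytosine: position, context, and TSS-relative label."""

    position: int
    context: str
    motif_start: int
    strand: str = "+"
    tss_label: int = 0
    proximal_pair_member: bool = False


@dataclass(frozen=True)
class ReferenceRegion:
    """The unconverted genomic window under analysis.

    ``window`` is a 0-based half-open [start, end) slice of ``sequence``;
    only assayed cytosines inside the window are reported.
    """

    name: str
    sequence: str
    tss_index: int
    window: tuple[int, int]
    snp: Optional[SnpSpec] = None
    motifs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS
    proximal_pair: Optional[tuple[int, int]] = None  # positions of the (CCWGG)2 assayed Cs

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "motifs", tuple(self.motifs))
        for base in seq:
            if base not in _IUPAC:
                raise ConfigurationError(f"sequence contains non-IUPAC base {base!r}")
        if not 0 <= self.tss_index < len(seq):
            raise ConfigurationError("tss_index outside sequence")
        start, end = self.window
        if not (0 <= start < end <= len(seq)):
            raise ConfigurationError("window outside sequence bounds")
        object.__setattr__(self, "window", (start, end))
        if self.snp is not None:
            if not 0 <= self.snp.position < len(seq):
                raise ConfigurationError("SNP position outside sequence")
            ref_base = seq[self.snp.position]
            if ref_base not in self.snp.alleles:
                raise ConfigurationError(
                    f"reference base {ref_base!r} at SNP position is not one of the alleles"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def sites(self) -> list[MethylSite]:
        """All assayable sites of all configured motifs, ordered by position.

        The proximal (CCWGG)2 pair flag is taken from ``proximal_pair`` when
        set; otherwise the two CCWGG sites nearest the TSS are designated.
        """
        all_sites: list[MethylSite] = []
        for spec in self.motifs:
            all_sites.extend(scan_motifs(self, spec))
        all_sites.sort(key=lambda s: (s.position, s.context))
        pair = self.proximal_pair
        if pair is None:
            ccwgg = [s for s in all_sites if s.context == "CCWGG"]
            ccwgg.sort(key=lambda s: (abs(s.position - self.tss_index), s.position))
            pair = tuple(sorted(s.position for s in ccwgg[:2]))
        pair_set = set(pair or ())
        return [
            replace(s, proximal_pair_member=(s.position in pair_set and s.context == "CCWGG"))
            for s in all_sites
        ]

    def assayed_positions(self) -> set[int]:
        """Positions of every assayed cytosine (any motif) inside the window."""
        return {s.position for s in self.sites()}


def scan_motifs(region: ReferenceRegion, spec: MotifSpec, strand: str = "+") -> list[MethylSite]:
    """Find every occurrence of ``spec`` whose assayed C lies in the window.

    Occurrences may overlap; all are reported, ordered by assayed position.
    ``strand='-'`` scans the reverse complement and reports positions in
    top-strand coordinates (off by default; one strand is amplified).
    """
    if strand == "+":
        seq = region.sequence
    elif strand == "-":
        seq = str(Seq(region.sequence).reverse_complement())
    else:
        raise ConfigurationError(f"strand must be '+' or '-', got {strand!r}")
    n = len(seq)
    k = len(spec.pattern)
    start, end = region.window
    sites = []
    for i in range(n - k + 1):
        if not spec.matches_at(seq, i):
            continue
        assayed = i + spec.assayed_offset
        pos = assayed if strand == "+" else n - 1 - assayed
        if not start <= pos < end:
            continue
        sites.append(
            MethylSite(
                position=pos,
                context=spec.name,
                motif_start=i if strand == "+" else n - (i + k),
                strand=strand,
                tss_label=tss_label(region, pos),
            )
        )
    sites.sort(key=lambda s: s.position)
    return sites


def convert_insilico(region: ReferenceRegion | str, methylated_positions: Iterable[int] = ()) -> str:
    """Bisulfite-convert a sequence in silico.

    Every C becomes T except Cs at ``methylated_positions`` (5mC resists
    conversion and still reads as C). Non-C bases are untouched.
    """
    seq = region.sequence if isinstance(region, ReferenceRegion) else region.upper()
    protected = set(methylated_positions)
    for pos in protected:
        if not 0 <= pos < len(seq) or seq[pos] != "C":
            raise ValueError(f"methylated position {pos} is not a C in the sequence")
    return "".join(
        "C" if (base == "C" and i in protected) else ("T" if base == "C" else base)
        for i, base in enumerate(seq)
    )


def alignment_reference(region: ReferenceRegion | str) -> str:
    """Reference with every C degenerated to Y (pyrimidine).

    Bisulfite reads carry C or T at former-C positions depending on
    methylation; aligning against the all-Y template is neutral to either
    state, so a single alignment serves both.
    """
    seq = region.sequence if isinstance(region, ReferenceRegion) else region.upper()
    return seq.replace("C", "Y")


def tss_label(region: ReferenceRegion, position: int) -> int:
    """TSS-relative label of ``position``: +1 at the TSS, no position 0."""
    if not 0 <= position < len(region.sequence):
        raise ValueError(f"position {position} outside sequence")
    if position >= region.tss_index:
        return position - region.tss_index + 1
    return position - region.tss_index


def position_from_tss_label(region: ReferenceRegion, label: int) -> int:
    """Inverse of :func:`tss_label`."""
    if label == 0:
        raise ValueError("TSS labels have no position 0")
    pos = region.tss_index + label - 1 if label > 0 else region.tss_index + label
    if not 0 <= pos < len(region.sequence):
        raise ValueError(f"label {label} outside sequence")
    return pos
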