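"""Readers, writers and the text lollipop rendering.

FASTA goes through Biopython's SeqIO with light validation on top
(empty files and empty sequences are rejected with the offending record
named). Region configuration is YAML; clone reports are TSV/JSON with
stable, documented columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .patterns import SampleProfile
from .pipeline import CloneReport
from .reference import MotifSpec, ReferenceRegion, SnpSpec

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_region_config",
    "write_region_config",
    "reports_to_frame",
    "write_reports",
    "profile_to_dict",
    "write_profile",
    "read_ct_table",
    "render_lollipop",
]


class FastaError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; multi-line records fine, case folded to upper."""
    path = Path(path)
    records = []
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            if not seq:
                raise FastaError(f"{path}: record {record.id!r} has an empty sequence")
            records.append((record.id, seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_region_config(fasta_path: str | Path, config_path: str | Path) -> ReferenceRegion:
    """Assemble a ReferenceRegion from a single-record FASTA + YAML config.

    Config keys: ``tss`` (0-based index), ``window`` ([start, end)),
    optional ``snp`` {pos, ref_allele, alt_allele, label}, optional
    ``motifs`` [{name, pattern, assayed_offset}], optional
    ``proximal_pair`` ([pos, pos]).
    """
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise FastaError(f"{fasta_path}: expected exactly one reference record, got {len(records)}")
    name, sequence = records[0]
    with open(config_path) as handle:
        cfg = yaml.safe_load(handle)
    snp = None
    if cfg.get("snp"):
        s = cfg["snp"]
        snp = SnpSpec(int(s["pos"]), s["ref_allele"], s["alt_allele"], s.get("label", ""))
    kwargs = {}
    if cfg.get("motifs"):
        kwargs["motifs"] = tuple(
            MotifSpec(m["name"], m["pattern"], int(m["assayed_offset"])) for m in cfg["motifs"]
        )
    if cfg.get("proximal_pair"):
        kwargs["proximal_pair"] = tuple(int(p) for p in cfg["proximal_pair"])
    return ReferenceRegion(
        name=cfg.get("name", name),
        sequence=sequence,
        tss_index=int(cfg["tss"]),
        window=tuple(int(x) for x in cfg["window"]),
        snp=snp,
        **kwargs,
    )


def write_region_config(region: ReferenceRegion, fasta_path: str | Path,
                        config_path: str | Path) -> None:
    write_fasta([(region.name, region.sequence)], fasta_path)
    cfg = {
        "name": region.name,
        "tss": region.tss_index,
        "window": list(region.window),
        "motifs": [
            {"name": m.name, "pattern": m.pattern, "assayed_offset": m.assayed_offset}
            for m in region.motifs
        ],
    }
    if region.snp is not None:
        cfg["snp"] = {
            "pos": region.snp.position,
            "ref_allele": region.snp.ref_allele,
            "alt_allele": region.snp.alt_allele,
            "label": region.snp.label,
        }
    pair = [s.position for s in region.sites() if s.proximal_pair_member]
    if pair:
        cfg["proximal_pair"] = pair
    with open(config_path, "w") as handle:
        yaml.safe_dump(cfg, handle, sort_keys=False)


_STATE_CODE = {"methylated": "M", "unmethylated": "U", "ambiguous": "A"}


def reports_to_frame(reports: Sequence[CloneReport], region: ReferenceRegion) -> pd.DataFrame:
    """One row per clone: id, efficiency, QC verdict, allele, then one M/U/A
    column per assayed site (named by context and TSS label)."""
    site_cols = [f"{s.context}_{s.tss_label:+d}" for s in region.sites()]
    rows = []
    for report in reports:
        row = {
            "clone_id": report.clone_id,
            "conversion_efficiency": report.conversion_efficiency,
            "n_converted_c": report.n_converted_c,
            "n_eligible_c": report.n_eligible_c,
            "passes_qc": report.passes_qc,
            "omit_reason": report.omit_reason or "",
            "allele": report.allele,
        }
        for col, call in zip(site_cols, report.site_calls):
            row[col] = _STATE_CODE[call.state]
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(reports: Sequence[CloneReport], region: ReferenceRegion,
                  tsv_path: str | Path, json_path: Optional[str | Path] = None) -> None:
    frame = reports_to_frame(reports, region)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as handle:
            json.dump(frame.to_dict(orient="records"), handle, indent=2)


def profile_to_dict(profile: SampleProfile) -> dict:
    return {
        "sample": profile.sample,
        "genotype": profile.genotype,
        "genotype_alleles": list(profile.genotype_alleles),
        "promoter_state": profile.promoter_state,
        "association_p": profile.association_p,
        "n_passed": profile.n_passed,
        "n_omitted": profile.n_omitted,
        "clone_counts": [
            {"allele": allele, "class": cls, "count": count}
            for (allele, cls), count in sorted(profile.clone_counts.items())
        ],
    }


def write_profile(profile: SampleProfile, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(profile_to_dict(profile), handle, indent=2)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample, gene, replicate, ct."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "ct"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing Ct table columns {sorted(missing)}")
    return frame


_LOLLIPOP = {
    "CpG": {"methylated": "●", "unmethylated": "○", "ambiguous": "?"},
    "other": {"methylated": "▲", "unmethylated": "△", "ambiguous": "?"},
}


def render_lollipop(reports: Sequence[CloneReport], region: ReferenceRegion) -> str:
    """Plain-text per-clone methylation map, rows grouped by allele.

    CpG sites render as filled/open circles, CCWGG (and any other motif)
    sites as filled/open triangles; '?' marks ambiguous calls.
    """
    sites = region.sites()
    header = "allele  clone" + " " * 16 + " ".join(
        f"{s.tss_label:+d}" for s in sites
    )
    lines = [header]
    for report in sorted(reports, key=lambda r: (r.allele, r.clone_id)):
        symbols = []
        for call in report.site_calls:
            family = "CpG" if call.site.context == "CpG" else "other"
            symbols.append(_LOLLIPOP[family][call.state])
        lines.append(f"{report.allele:>6}  {report.clone_id:<20} " + "  ".join(symbols))
    return "\n".join(lines)
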