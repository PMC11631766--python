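"""Readers/writers for the pipeline's file surface.

FASTA/FASTQ go through Biopython; tables are TSV via pandas with fixed
formatting (floats to 6 decimals, missing rates as ``NA``) so they
round-trip losslessly. BED output is 0-based half-open. FASTA record ids
use "|"-delimited composite keys: ``<fusion key>|<site key>|<REC|UNREC>``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import (
    FusionDesign,
    FusionMode,
    RecombinationState,
    ReferenceAmplicon,
    TargetSiteDesign,
)
from .motifs import MotifHit
from .screen import RateRecord, Read, RunStats

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_references",
    "read_references",
    "build_manifest",
    "write_manifest",
    "read_manifest",
    "write_rate_table",
    "read_rate_table",
    "write_assignment_table",
    "write_heatmap_table",
    "motif_hits_to_bed",
    "write_bed",
    "RunLog",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fastq(path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.asarray(rec.letter_annotations["phred_quality"], dtype=float),
            )
        )
    return reads


def write_fastq(path, reads: Iterable[Read]) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            q = r.qualities if r.qualities is not None else np.zeros(len(r.sequence))
            rec.letter_annotations["phred_quality"] = [
                int(round(min(max(x, 0), 93))) for x in q
            ]
            yield rec

    SeqIO.write(records(), str(path), "fastq")


def write_references(
    amplicons: Sequence[ReferenceAmplicon], fasta_path, bed_path=None
) -> None:
    """Multi-FASTA of reference amplicons plus a BED of their annotations."""
    write_fasta(fasta_path, {a.fasta_id: a.sequence for a in amplicons})
    if bed_path is not None:
        rows = []
        for a in amplicons:
            for name, ivs in sorted(a.annotations.items()):
                for s, e in ivs:
                    rows.append((a.fasta_id, s, e, name))
        write_bed(bed_path, rows)


def read_references(fasta_path, bed_path=None) -> list[ReferenceAmplicon]:
    seqs = read_fasta(fasta_path)
    ann: dict[str, dict[str, list[tuple[int, int]]]] = {rid: {} for rid in seqs}
    if bed_path is not None:
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, name = line.rstrip("\n").split("\t")[:4]
                ann.setdefault(chrom, {}).setdefault(name, []).append((int(s), int(e)))
    out = []
    for rid, seq in seqs.items():
        variant_id, _, state = rid.rpartition("|")
        out.append(
            ReferenceAmplicon(
                variant_id=variant_id,
                state=RecombinationState(state),
                sequence=seq,
                annotations=ann.get(rid, {}),
            )
        )
    return out


def write_bed(path, rows: Iterable[Sequence]) -> None:
    """Write BED rows (0-based half-open intervals) as TSV."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def motif_hits_to_bed(hits: Sequence[MotifHit]) -> list[tuple]:
    """BED6 rows (+ p-value in column 7) for motif hits."""
    return [
        (h.seq_id, h.start, h.end, "motif", f"{h.score:.6f}", h.strand, f"{h.p_value:.3e}")
        for h in hits
    ]


# ---------------------------------------------------------------------------
# design manifest


def build_manifest(
    fusion_designs: Sequence[FusionDesign], site_designs: Sequence[TargetSiteDesign]
) -> pd.DataFrame:
    """Design-space table: one row per fusion × site variant."""
    rows = []
    for f in fusion_designs:
        for s in site_designs:
            rows.append(
                {
                    "variant_id": f"{f.key}|{s.key}",
                    "mode": f.mode.value,
                    "linker_left": f.linker_left_repeats,
                    "linker_right": f.linker_right_repeats
                    if f.mode is FusionMode.INSERTIONAL
                    else 0,
                    "spacing": s.spacing_bp if s.motif is not None else pd.NA,
                    "orientation": s.orientation.value if s.motif is not None else pd.NA,
                    "site_name": s.key,
                    "flanked": s.flanked_sides.value,
                }
            )
    return pd.DataFrame(rows)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"orientation": "string"})
    return df


# ---------------------------------------------------------------------------
# rate / assignment / heat-map tables

_RATE_COLUMNS = ["variant_id", "n_rec", "n_unrec", "rate", "odds"]


def write_rate_table(records: Sequence[RateRecord], path) -> None:
    """TSV rate table with stable column order and 6-decimal floats."""
    key_cols: list[str] = []
    for r in records:
        for k in r.key:
            if k not in key_cols:
                key_cols.append(k)
    with open(path, "w") as fh:
        fh.write("\t".join(_RATE_COLUMNS[:3] + key_cols + _RATE_COLUMNS[3:]) + "\n")
        for r in records:
            fmt = lambda v: "NA" if v is None or pd.isna(v) else (
                f"{v:.6f}" if isinstance(v, float) else str(v)
            )
            vals = [r.variant_id, r.n_rec, r.n_unrec]
            vals += [r.key.get(k) for k in key_cols]
            vals += [r.rate, r.odds]
            fh.write("\t".join(fmt(v) for v in vals) + "\n")


def read_rate_table(path) -> list[RateRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"orientation": "string"})
    records = []
    key_cols = [c for c in df.columns if c not in _RATE_COLUMNS]
    for _, row in df.iterrows():
        key = {}
        for k in key_cols:
            v = row[k]
            key[k] = None if pd.isna(v) else v
        records.append(
            RateRecord(
                variant_id=row["variant_id"],
                n_rec=int(row["n_rec"]),
                n_unrec=int(row["n_unrec"]),
                key=key,
            )
        )
    return records


def write_assignment_table(assignments, path) -> None:
    rows = []
    for a in assignments:
        rows.append(
            {
                "read_id": a.read_id,
                "variant_id": a.variant_id if a.assigned else "UNASSIGNED",
                "state": a.state.value if a.state is not None else "UNDETERMINED",
                "score": a.score,
                "margin": a.margin,
                "strand": a.strand,
                "flags": ",".join(sorted(a.flags)) or ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_heatmap_table(heatmap, path) -> None:
    heatmap.rates.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


# ---------------------------------------------------------------------------
# run log


@dataclass
class RunLog:
    """Timestamped per-stage records with read accounting."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages.append(
            {
                "time": _dt.datetime.now().isoformat(timespec="seconds"),
                "stage": stage,
                **counts,
            }
        )

    def record_stats(self, stage: str, stats: RunStats) -> None:
        stats.check_conservation()
        self.record(
            stage,
            reads_in=stats.n_input,
            low_quality=stats.n_low_quality,
            ambiguous=stats.n_ambiguous,
            no_coverage=stats.n_no_coverage,
            assigned=stats.n_assigned,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.stages:
                fh.write("\t".join(f"{k}={v}" for k, v in s.items()) + "\n")
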