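"""Shared file I/O: FASTA, region tables and generic CSV/TSV tables.

Region tables are TSV with columns seq_id, region, start, end using
0-based half-open coordinates (a ``# coordinates: 0-based half-open``
header line is written and tolerated on read).  Converters from 1-based
inclusive coordinates are provided.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import AnnotatedIgV

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_region_table",
    "write_region_table",
    "read_table",
    "write_table",
    "read_annotated_igv",
    "write_annotated_igv",
    "one_based_to_interval",
]

_REGION_COLUMNS = ["seq_id", "region", "start", "end"]
_COORD_HEADER = "# coordinates: 0-based half-open"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_region_table(path: str | Path) -> pd.DataFrame:
    """Read a region TSV (seq_id, region, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_REGION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region table {path} missing columns: {sorted(missing)}")
    df = df[_REGION_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df[(df["start"] < 0) | (df["end"] <= df["start"])]
    if not bad.empty:
        raise ValueError(f"invalid intervals for seq_ids: {sorted(bad['seq_id'].unique())}")
    return df


def write_region_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER + "\n")
        df[_REGION_COLUMNS].to_csv(fh, sep="\t", index=False)


def one_based_to_interval(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start_1based < 1 or end_inclusive < start_1based:
        raise ValueError("invalid 1-based interval")
    return start_1based - 1, end_inclusive


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV (default) or TSV table by file extension."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, comment="#")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_annotated_igv(
    fasta_path: str | Path, regions_path: str | Path, species_map: Mapping[str, str] | None = None
) -> list[AnnotatedIgV]:
    """Load sequences plus their region annotations into AnnotatedIgV objects.

    Interval bounds are validated against sequence lengths; a region row for
    an unknown seq_id is an error.
    """
    seqs = read_fasta(fasta_path)
    regions = read_region_table(regions_path)
    unknown = sorted(set(regions["seq_id"]) - set(seqs))
    if unknown:
        raise ValueError(f"region rows for unknown sequences: {unknown}")
    out = []
    for seq_id, seq in seqs.items():
        sub = regions[regions["seq_id"] == seq_id]
        region_map = {
            str(r.region): (int(r.start), int(r.end)) for r in sub.itertuples(index=False)
        }
        species = species_map.get(seq_id, "") if species_map else ""
        out.append(
            AnnotatedIgV(seq_id=seq_id, sequence=seq, regions=region_map, species_id=species)
        )
    return out


def write_annotated_igv(
    seqs: Sequence[AnnotatedIgV], fasta_path: str | Path, regions_path: str | Path
) -> None:
    write_fasta({s.seq_id: s.sequence for s in seqs}, fasta_path)
    rows = [
        {"seq_id": s.seq_id, "region": region, "start": start, "end": end}
        for s in seqs
        for region, (start, end) in sorted(s.regions.items(), key=lambda kv: kv[1][0])
    ]
    write_region_table(pd.DataFrame(rows, columns=_REGION_COLUMNS), regions_path)
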