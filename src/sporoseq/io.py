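"""Readers and writers for the plain-text formats the pipeline exchanges.

Transcript sequences travel as FASTA, locus metadata / count matrices /
sample sheets / hit tables as tab-separated text.  Similarity hit tables use
the 12-column BLAST tabular layout (``-outfmt 6``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import TranscriptRecord

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

LOCUS_COLUMNS = ["transcript_id", "scaffold", "strand", "rank", "start", "end"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (order-preserving)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def write_loci(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": r.id,
            "scaffold": r.scaffold,
            "strand": r.strand,
            "rank": r.rank,
            "start": r.start,
            "end": r.end,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_transcripts(fasta: str | Path, loci: str | Path | None = None) -> list[TranscriptRecord]:
    """Assemble TranscriptRecords from a FASTA file plus an optional locus TSV."""
    seqs = read_fasta(fasta)
    meta: dict[str, dict] = {}
    if loci is not None:
        df = pd.read_csv(loci, sep="\t", dtype={"transcript_id": str, "scaffold": str})
        for row in df.itertuples(index=False):
            meta[row.transcript_id] = {
                "scaffold": None if pd.isna(row.scaffold) else str(row.scaffold),
                "strand": None if pd.isna(row.strand) else str(row.strand),
                "rank": None if pd.isna(row.rank) else int(row.rank),
                "start": None if pd.isna(row.start) else int(row.start),
                "end": None if pd.isna(row.end) else int(row.end),
            }
    return [
        TranscriptRecord(id=tid, sequence=seq, **meta.get(tid, {}))
        for tid, seq in seqs.items()
    ]


def read_blast6(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular file; malformed rows are dropped.

    Returns the table with standard column names plus an attribute
    ``n_rejected`` counting rejected rows.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=BLAST6_COLUMNS, dtype=str, comment="#"
    )
    n_in = len(df)
    numeric = {
        "pident": float,
        "length": int,
        "mismatch": int,
        "gapopen": int,
        "qstart": int,
        "qend": int,
        "sstart": int,
        "send": int,
        "evalue": float,
        "bitscore": float,
    }
    for col, typ in numeric.items():
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=list(numeric)).copy()
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[col] = df[col].astype(int)
    df.attrs["n_rejected"] = n_in - len(df)
    return df.reset_index(drop=True)


def write_blast6(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BLAST6_COLUMNS)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a transcripts x samples count matrix (first column = transcript id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df.astype(int)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet with columns sample_id, experiment, strain, timepoint_h."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "experiment", "strain", "timepoint_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    df["timepoint_h"] = df["timepoint_h"].astype(int)
    return df


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
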