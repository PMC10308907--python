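"""Readers and writers for the pipeline's external formats.

FASTA in/out goes through Biopython; BLAST/DIAMOND tabular hit files
(outfmt 6 style) are parsed with pandas with a configurable column map.
Gzip-compressed FASTA is accepted transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orfs import Contig, HitRecord, OrfCall

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_orf_table",
    "write_peptides",
    "OUTFMT6_COLUMNS",
]

#: the standard 12 columns of BLAST/DIAMOND -outfmt 6
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a (possibly gzipped) multi-FASTA into contigs, order preserved."""
    with _open_text(path) as fh:
        return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(contigs: Sequence[Contig], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.contig_id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_hit_table(
    path: str | Path, columns: Sequence[str] = OUTFMT6_COLUMNS
) -> list[HitRecord]:
    """Parse a tabular homology-hit file into :class:`HitRecord` rows.

    ``columns`` names the file's columns; it must include qseqid, sseqid,
    pident, evalue and bitscore.  An optional ``staxids``/``stitle`` column
    is carried as the subject taxon.  Malformed rows raise with the line
    number.
    """
    required = {"qseqid", "sseqid", "pident", "evalue", "bitscore"}
    missing = required - set(columns)
    if missing:
        raise ValueError(f"hit-table column map lacks {sorted(missing)}")
    try:
        df = pd.read_csv(path, sep="\t", names=list(columns), comment="#")
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise ValueError(f"cannot parse hit table {path}: {exc}") from exc
    taxon_col = next((c for c in ("staxids", "stitle") if c in columns), None)
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            hits.append(
                HitRecord(
                    query_id=str(getattr(row, "qseqid")),
                    subject_id=str(getattr(row, "sseqid")),
                    percent_identity=float(getattr(row, "pident")) / 100.0,
                    evalue=float(getattr(row, "evalue")),
                    bitscore=float(getattr(row, "bitscore")),
                    subject_taxon=(
                        str(getattr(row, taxon_col)) if taxon_col else None
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed hit record at line {i}: {exc}") from exc
    return hits


ORF_TABLE_COLUMNS = (
    "contig_id", "table_id", "strand", "frame", "start", "end",
    "aa_len", "has_terminal_stop", "used_alt_start",
)


def write_orf_table(calls: Sequence[OrfCall], path: str | Path) -> None:
    """TSV of ORF calls (one row per call, fixed column order)."""
    rows = [
        {
            "contig_id": c.contig_id,
            "table_id": c.table_id,
            "strand": c.strand,
            "frame": c.frame,
            "start": c.start,
            "end": c.end,
            "aa_len": c.aa_len,
            "has_terminal_stop": c.has_terminal_stop,
            "used_alt_start": c.used_alt_start,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=ORF_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_peptides(calls: Sequence[OrfCall], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.peptide), id=c.orf_id, description=f"table={c.table_id}")
        for c in calls
    ]
    SeqIO.write(records, str(path), "fasta")
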