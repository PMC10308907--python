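"""UGA-readthrough analysis: dependence of an ORF on mitochondrial decoding.

A transcript whose ORF contains in-frame UGA codons yields a full-length
product only on mitochondrial ribosomes, where UGA is decoded as tryptophan;
cytosolic ribosomes terminate at the first UGA.  This module counts in-frame
UGA codons per ORF and compares peptide lengths under mitochondrial versus
standard (cytosolic) decoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .orfs import Contig, OrfCall

__all__ = [
    "ReadthroughReport",
    "count_uga",
    "dual_decode_lengths",
    "analyze_orf",
    "summarize_readthrough",
    "CYTO_STOPS",
]

#: standard-code (cytosolic) termination codons
CYTO_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class ReadthroughReport:
    orf_id: str
    table_id: int
    n_uga: int
    len_mito_aa: int
    len_standard_aa: int
    requires_mito: bool
    group: str = "all"


def _codons(orf: OrfCall, contig: Contig) -> list[str]:
    nt = orf.coding_nt(contig)  # terminal stop already excluded
    return [nt[i : i + 3] for i in range(0, len(nt), 3)]


def count_uga(orf: OrfCall, contig: Contig) -> int:
    """Number of in-frame TGA triplets inside the coding region.

    The terminal stop codon (when present) is excluded: the count concerns
    tryptophans in the RdRp product, not termination.
    """
    return sum(c == "TGA" for c in _codons(orf, contig))


def dual_decode_lengths(
    orf: OrfCall, contig: Contig, cyto_stops: frozenset[str] = CYTO_STOPS
) -> tuple[int, int]:
    """Peptide lengths under mitochondrial vs cytosolic decoding.

    Returns ``(len_mito_aa, len_standard_aa)``: the mitochondrial length is
    the called peptide length; the standard length is the number of residues
    a cytosolic ribosome would synthesise before hitting the first codon in
    ``cyto_stops``, scanning the same frame from the same start.
    """
    codons = _codons(orf, contig)
    len_mito = len(orf.peptide)
    len_standard = len_mito
    for i, c in enumerate(codons):
        if c in cyto_stops:
            len_standard = i
            break
    return len_mito, len_standard


def analyze_orf(
    orf: OrfCall, contig: Contig, group: str = "all"
) -> ReadthroughReport:
    n_uga = count_uga(orf, contig)
    len_mito, len_standard = dual_decode_lengths(orf, contig)
    return ReadthroughReport(
        orf_id=orf.orf_id,
        table_id=orf.table_id,
        n_uga=n_uga,
        len_mito_aa=len_mito,
        len_standard_aa=len_standard,
        requires_mito=n_uga >= 1,
        group=group,
    )


_SUMMARY_COLUMNS = [
    "group",
    "n_orfs",
    "n_requires_mito",
    "frac_requires_mito",
    "median_n_uga",
    "max_n_uga",
    "median_len_mito_aa",
    "median_len_standard_aa",
]


def summarize_readthrough(reports: Iterable[ReadthroughReport]) -> pd.DataFrame:
    """Per-group counts and fractions of mitochondrial-decoding dependence.

    One row per group, ordered by group label; an empty input yields an
    empty frame with the full column schema.
    """
    rows = [
        {
            "group": r.group,
            "n_uga": r.n_uga,
            "requires_mito": r.requires_mito,
            "len_mito_aa": r.len_mito_aa,
            "len_standard_aa": r.len_standard_aa,
        }
        for r in reports
    ]
    if not rows:
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group", sort=True)
        .agg(
            n_orfs=("n_uga", "size"),
            n_requires_mito=("requires_mito", "sum"),
            frac_requires_mito=("requires_mito", "mean"),
            median_n_uga=("n_uga", "median"),
            max_n_uga=("n_uga", "max"),
            median_len_mito_aa=("len_mito_aa", "median"),
            median_len_standard_aa=("len_standard_aa", "median"),
        )
        .reset_index()
    )
    return out[_SUMMARY_COLUMNS]
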