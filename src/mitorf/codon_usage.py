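"""Codon usage bias: frequency vectors, Pearson R² correlation, heatmaps.

A virus translated on mitochondrial ribosomes is expected to mirror the
codon usage of mitochondrially encoded genes rather than nuclear
transcripts.  This module computes 64-entry codon-frequency vectors for
ORFs and reference CDS sets, correlates them with Pearson's R², and
assigns each query to its best-matching reference compartment.

Frequencies are global codon fractions (counts / total codons), not
per-amino-acid RSCU; an RSCU mode is available for sensitivity analysis.
The default correlation uses all 64 codons (stop-codon identity differs
across genetic codes, so cross-table comparability requires counting raw
triplets); a 61-sense-codon mode is available.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genetic_codes import CODONS, get_code

__all__ = [
    "CodonUsageTable",
    "codon_frequencies",
    "build_reference_table",
    "read_usage_table",
    "write_usage_table",
    "pearson_r2",
    "rscu",
    "correlate_all",
    "CorrelationMatrix",
]

_CODON_POS = {c: i for i, c in enumerate(CODONS)}
#: codons that are sense under the standard code (61 triplets)
SENSE_CODONS = tuple(c for c in CODONS if get_code(1).codon_to_aa[c] != "*")
_SENSE_MASK = np.array([get_code(1).codon_to_aa[c] != "*" for c in CODONS])


@dataclass(frozen=True)
class CodonUsageTable:
    """A 64-entry codon count/frequency vector with a source label."""

    label: str
    counts: np.ndarray  # int64[64] in CODONS order

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (64,):
            raise ValueError("counts must be a 64-vector in codon order")
        if (arr < 0).any():
            raise ValueError("codon counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def n_codons(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        n = self.n_codons
        if n == 0:
            return np.zeros(64)
        return self.counts / n

    def freq(self, codon: str) -> float:
        return float(self.freqs[_CODON_POS[codon]])

    def count(self, codon: str) -> int:
        return int(self.counts[_CODON_POS[codon]])


def codon_frequencies(
    coding_seqs: Iterable[str],
    label: str = "query",
    stop_codons: frozenset[str] = frozenset(),
    on_remainder: str = "error",
) -> CodonUsageTable:
    """Pooled codon counts over complete codons of all sequences.

    A terminal codon found in ``stop_codons`` is trimmed before counting
    (pass the resolved genetic code's stop set to exclude terminal stops).
    N-containing codons are skipped.  A sequence whose length is not a
    multiple of 3 after trimming raises by default; ``on_remainder="trim"``
    drops the trailing remainder instead.
    """
    if on_remainder not in ("error", "trim"):
        raise ValueError("on_remainder must be 'error' or 'trim'")
    counts = np.zeros(64, dtype=np.int64)
    for rec_no, seq in enumerate(coding_seqs):
        s = seq.upper().replace("U", "T")
        if len(s) % 3:
            if on_remainder == "error":
                raise ValueError(
                    f"record {rec_no} has length {len(s)}, not a multiple of 3"
                )
            s = s[: len(s) - len(s) % 3]
        if s[-3:] in stop_codons:
            s = s[:-3]
        for i in range(0, len(s), 3):
            pos = _CODON_POS.get(s[i : i + 3])
            if pos is not None:  # codons containing N (or gaps) are skipped
                counts[pos] += 1
    return CodonUsageTable(label=label, counts=counts)


def build_reference_table(cds_fasta: str | Path, label: str) -> CodonUsageTable:
    """Pooled codon usage of a reference CDS FASTA (e.g. mitochondrial CDS)."""
    from .io import read_fasta

    records = read_fasta(cds_fasta)
    if not records:
        raise ValueError(f"no CDS records in {cds_fasta}")
    return codon_frequencies(
        (c.seq for c in records), label=label, stop_codons=CYTO_AND_MITO_STOPS
    )


#: union of termination codons across tables 1/2/4/5, used when trimming
#: terminal stops from reference CDS of unknown compartment
CYTO_AND_MITO_STOPS = frozenset({"TAA", "TAG", "TGA", "AGA", "AGG"})


def write_usage_table(table: CodonUsageTable, path: str | Path) -> None:
    """Write a usage table as TSV: header lines, then codon/count/frequency."""
    with open(path, "w") as fh:
        fh.write(f"# label\t{table.label}\n# n_codons\t{table.n_codons}\n")
        fh.write("codon\tcount\tfrequency\n")
        for c, n, f in zip(CODONS, table.counts, table.freqs):
            fh.write(f"{c}\t{int(n)}\t{f:.10g}\n")


def read_usage_table(path: str | Path, label: str | None = None) -> CodonUsageTable:
    """Read a codon usage TSV.

    Accepts this package's codon/count/frequency layout as well as
    HIVE-style tables whose numeric column is a per-1000 frequency (values
    are renormalised, and fractional columns are converted to pseudo-counts
    scaled to preserve relative usage).
    """
    path = Path(path)
    header_label = None
    lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            parts = line.lstrip("# ").split("\t")
            if len(parts) == 2 and parts[0] == "label":
                header_label = parts[1]
        elif line.strip():
            lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    codon_col = next((c for c in df.columns if c in ("codon", "triplet")), None)
    if codon_col is None:
        raise ValueError(f"{path}: no codon column found")
    value_col = next(
        (c for c in df.columns if c in ("count", "number", "frequency", "per1000", "per_1000")),
        None,
    )
    if value_col is None:
        raise ValueError(f"{path}: no count/frequency column found")
    counts = np.zeros(64, dtype=np.int64)
    for codon, value in zip(df[codon_col], df[value_col]):
        codon = str(codon).strip().upper().replace("U", "T")
        if codon not in _CODON_POS:
            raise ValueError(f"{path}: unrecognised codon {codon!r}")
        if value_col == "count":
            counts[_CODON_POS[codon]] = int(value)
        else:
            # fractional usage (frequency or per-1000): scale to pseudo-counts
            counts[_CODON_POS[codon]] = int(round(float(value) * 1_000_000))
    return CodonUsageTable(label=label or header_label or path.stem, counts=counts)


def _subset_mask(codon_subset: str) -> np.ndarray:
    if codon_subset == "all64":
        return np.ones(64, dtype=bool)
    if codon_subset == "sense_only":
        return _SENSE_MASK
    raise ValueError("codon_subset must be 'all64' or 'sense_only'")


def pearson_r2(
    a: CodonUsageTable, b: CodonUsageTable, codon_subset: str = "all64"
) -> float:
    """Square of the Pearson correlation of two codon-frequency vectors."""
    mask = _subset_mask(codon_subset)
    x, y = a.freqs[mask], b.freqs[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"zero-variance codon usage vector ({a.label!r} vs {b.label!r}): "
            "Pearson correlation is undefined"
        )
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def rscu(table: CodonUsageTable) -> np.ndarray:
    """Relative synonymous codon usage under the standard code (sensitivity mode).

    Stop codons get RSCU 0; unobserved synonymous families get 0 across
    the family.
    """
    code = get_code(1)
    out = np.zeros(64)
    families: dict[str, list[int]] = {}
    for i, c in enumerate(CODONS):
        aa = code.codon_to_aa[c]
        if aa != "*":
            families.setdefault(aa, []).append(i)
    for idxs in families.values():
        fam_counts = np.array([table.counts[i] for i in idxs], dtype=float)
        tot = fam_counts.sum()
        if tot > 0:
            out[idxs] = fam_counts * len(idxs) / tot
    return out


@dataclass
class CorrelationMatrix:
    """Grid of R² values: one row per query ORF, one column per reference."""

    values: pd.DataFrame  # rows = query ids, cols = reference labels
    best_match: pd.Series = field(init=False)
    tie: pd.Series = field(init=False)
    row_order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        v = self.values
        # fixed reference ordering resolves ties (difference < 1e-12)
        best_idx = v.to_numpy().argmax(axis=1)
        best = v.columns[best_idx]
        row_max = v.to_numpy().max(axis=1, initial=-np.inf)
        tie = ((row_max[:, None] - v.to_numpy()) < 1e-12).sum(axis=1) > 1
        self.best_match = pd.Series(best, index=v.index, name="best_match")
        self.tie = pd.Series(tie, index=v.index, name="tie")
        self.row_order = _dendrogram_order(v)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out["best_match"] = self.best_match
        out["tie"] = self.tie
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().loc[self.row_order].to_csv(
            path, sep="\t", index_label="orf_id"
        )


def _dendrogram_order(values: pd.DataFrame) -> list[str]:
    """Row order by average-linkage clustering on (1 − r²) distance.

    Presentation only — mirrors heatmap row clustering on correlation
    values.  Degenerate shapes fall back to input order.
    """
    if len(values) < 3 or values.shape[1] < 2:
        return list(values.index)
    d = np.sqrt(((values.to_numpy()[:, None, :] - values.to_numpy()[None, :, :]) ** 2).sum(-1))
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    return [values.index[i] for i in leaves]


def correlate_all(
    orfs: Sequence[tuple[str, str]],
    refs: Sequence[CodonUsageTable],
    codon_subset: str = "all64",
    stop_codons: frozenset[str] = frozenset(),
) -> CorrelationMatrix:
    """Correlate each ORF's codon usage against every reference table.

    ``orfs`` is a sequence of ``(orf_id, coding_seq)`` pairs (coding
    sequence without, or with, its terminal stop — pass ``stop_codons`` to
    trim).  Reference labels must be unique.
    """
    if not refs:
        raise ValueError("at least one reference table is required")
    labels = [r.label for r in refs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate reference labels: {labels}")
    rows = {}
    for orf_id, seq in orfs:
        q = codon_frequencies([seq], label=orf_id, stop_codons=stop_codons)
        rows[orf_id] = [pearson_r2(q, ref, codon_subset) for ref in refs]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    values.index.name = "orf_id"
    return CorrelationMatrix(values=values)
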