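"""Composition and abundance statistics.

AT content of contigs (mitoviral genomes are markedly AT-rich, like the
mitochondrial genomes of their putative hosts), Mann–Whitney U group
comparisons, and RPKM abundance from read-mapping results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from scipy import stats as sps

__all__ = [
    "AbundanceRecord",
    "GroupComparison",
    "at_content",
    "mann_whitney",
    "rpkm",
    "count_mapped",
]


@dataclass(frozen=True)
class AbundanceRecord:
    contig_id: str
    mapped_reads: int
    contig_len_bp: int
    total_reads: int

    @property
    def rpkm(self) -> float:
        return rpkm(self.mapped_reads, self.contig_len_bp, self.total_reads)


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    direction: int  # sign of median(a) − median(b)
    method: str


def at_content(seq: str) -> float:
    """Fraction of A and T (or U) bases; N counts in the denominator only."""
    if not seq:
        raise ValueError("AT content of an empty sequence is undefined")
    s = seq.upper()
    return (s.count("A") + s.count("T") + s.count("U")) / len(s)


# maximum number of pooled arrangements enumerated when ties force a full
# permutation null (C(n_a+n_b, n_a) above this → normal approximation)
_MAX_ENUM = 200_000


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Mann–Whitney U test between two samples.

    The reported ``u_statistic`` is U for sample ``a`` (number of pairs
    where a-value exceeds b-value, ties counting one half), so
    0 ≤ U ≤ n_a·n_b.  ``alternative="greater"`` tests whether ``a`` tends
    larger than ``b``.

    Method selection: the exact U null distribution when there are no ties
    and n_a·n_b ≤ 400; full enumeration of pooled rearrangements when ties
    are present and the arrangement count is tractable; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError(
            "all pooled values identical: rank variance is zero and the "
            "Mann-Whitney test is degenerate"
        )
    u_a = _u_statistic(x, y)
    n_a, n_b = x.size, y.size
    has_ties = np.unique(pooled).size < pooled.size
    scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[
        alternative
    ]
    if not has_ties and n_a * n_b <= 400:
        res = sps.mannwhitneyu(x, y, alternative=scipy_alt, method="exact")
        p, method = float(res.pvalue), "exact"
    elif has_ties and math.comb(n_a + n_b, n_a) <= _MAX_ENUM:
        p, method = _enumerated_pvalue(pooled, n_a, u_a, alternative), "enumeration"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative=scipy_alt, method="asymptotic", use_continuity=True
        )
        p, method = float(res.pvalue), "normal"
    direction = int(np.sign(np.median(x) - np.median(y)))
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        u_statistic=u_a,
        p_value=min(p, 1.0),
        direction=direction,
        method=method,
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midranks: R_x − n_x(n_x+1)/2."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2)


def _enumerated_pvalue(
    pooled: np.ndarray, n_a: int, u_obs: float, alternative: str
) -> float:
    """Exact p by enumerating every split of the pooled (multiset) values."""
    n = pooled.size
    ranks = sps.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2
    total = 0
    ge = le = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if u >= u_obs - eps:
            ge += 1
        if u <= u_obs + eps:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


def rpkm(mapped_reads: int, contig_len_bp: int, total_reads: int) -> float:
    """Mapped reads per kilobase of contig per million total reads."""
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be non-negative")
    if contig_len_bp < 1 or total_reads < 1:
        raise ValueError("contig_len_bp and total_reads must be positive")
    return mapped_reads / ((contig_len_bp / 1_000) * (total_reads / 1_000_000))


def count_mapped(
    sam_path: str | Path, include_secondary: bool = False
) -> tuple[dict[str, int], int]:
    """Per-reference mapped-read counts and the total read count from a SAM.

    By default counts primary alignments only (secondary and supplementary
    records excluded), one count per mapped read; ``total`` includes
    unmapped reads, matching a per-million-total-reads denominator over the
    whole sequencing run.  ``include_secondary=True`` counts every aligned
    record instead.
    """
    path = Path(sam_path)
    counts: dict[str, int] = {}
    total = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header has no reference (@SQ) lines")
        counts = {sq["SN"]: 0 for sq in fh.header["SQ"]}
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                if include_secondary and not rec.is_unmapped:
                    counts[rec.reference_name] += 1
                continue
            total += 1
            if not rec.is_unmapped:
                if rec.reference_name not in counts:
                    raise ValueError(
                        f"{path}: alignment to unknown reference {rec.reference_name!r}"
                    )
                counts[rec.reference_name] += 1
    return counts, total
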