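"""Independent reference implementations used only to check the package.

These are deliberately written with different algorithms and data paths
from the library code: a pair-enumeration ORF scanner over string codon
lists, a sum-formula Pearson correlation in pure Python floats, and a
brute-force Mann–Whitney null built by enumerating every split of the
pooled sample.
"""

from __future__ import annotations

import math
from itertools import combinations

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def orf_scan_oracle(
    seq: str,
    code,
    min_aa: int = 300,
    require_start: bool = True,
    allow_alt_starts: bool = True,
) -> list[tuple]:
    """Exhaustive (start, stop) pair enumeration in every frame and strand.

    Returns tuples (strand, frame, start, end, has_terminal_stop,
    used_alt_start, peptide) with forward-strand half-open coordinates,
    sorted by (strand, frame, start).
    """
    seq = seq.upper().replace("U", "T")
    start_set = set(code.start_codons) if allow_alt_starts else {"ATG"}
    stop_set = set(code.stop_codons)
    aa = code.codon_to_aa
    out = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        L = len(s)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, L - 2, 3)]
            m = len(codons)
            stops = [j for j, c in enumerate(codons) if c in stop_set]
            # earliest qualifying start paired with its next in-frame stop
            best: dict[int, int] = {}
            for i in range(m):
                if require_start:
                    if codons[i] not in start_set:
                        continue
                else:
                    if i != 0 and codons[i - 1] not in stop_set:
                        continue
                j = next((x for x in stops if x >= i), m)
                if j not in best or i < best[j]:
                    best[j] = i
            for j, i in sorted(best.items()):
                if j - i < min_aa:
                    continue
                truncated = j == m
                pep = "".join(aa.get(c, "X") if "N" not in c else "X" for c in codons[i:j])
                if require_start:
                    pep = "M" + pep[1:]
                lo = frame + 3 * i
                hi = frame + 3 * (j if truncated else j + 1)
                if strand == "-":
                    lo, hi = L - hi, L - lo
                out.append(
                    (
                        strand,
                        frame,
                        lo,
                        hi,
                        not truncated,
                        require_start and codons[i] != "ATG",
                        pep,
                    )
                )
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def call_tuple(call) -> tuple:
    """Project an OrfCall onto the oracle's tuple shape."""
    return (
        call.strand,
        call.frame,
        call.start,
        call.end,
        call.has_terminal_stop,
        call.used_alt_start,
        call.peptide,
    )


def pearson_r2_textbook(x, y) -> float:
    """Sum-formula Pearson r², in pure Python floats."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    return r * r


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def mann_whitney_bruteforce(a, b, alternative: str = "two_sided") -> tuple[float, float]:
    """(U_a, p) by enumerating all C(n_a+n_b, n_a) splits of the pooled data."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = _midranks(pooled)
    offset = n_a * (n_a + 1) / 2
    u_obs = sum(ranks[: n_a]) - offset
    ge = le = total = 0
    eps = 1e-9
    for idx in combinations(range(len(pooled)), n_a):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if u >= u_obs - eps:
            ge += 1
        if u <= u_obs + eps:
            le += 1
    if alternative == "greater":
        p = ge / total
    elif alternative == "less":
        p = le / total
    else:
        p = min(1.0, 2 * min(ge, le) / total)
    return u_obs, p
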