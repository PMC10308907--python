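"""Six-frame ORF discovery under mitochondrial genetic codes.

Implements the contig-identification stage of the mitovirus discovery
pipeline: length-filter contigs, find ORFs in all six translational contexts
under each requested codon table, keep contigs with exactly one qualifying
ORF per table, and resolve multi-table calls with a fungal-mitochondrial
(table 4) preference.

ORF semantics follow the OrfFinder convention: within each stop-bounded
frame segment the ORF runs from the *first* qualifying start codon to the
next in-frame stop (nested shorter ORFs in the same segment are not
reported).  ORFs truncated by the contig edge are retained and flagged.
Coordinates are 0-based, half-open, always on the forward strand;
minus-strand ORFs report forward-strand projections plus a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_codes import GeneticCode, codon_indices, encode_sequence

__all__ = [
    "Contig",
    "OrfCall",
    "HitRecord",
    "filter_contigs",
    "find_orfs",
    "single_orf_filter",
    "resolve_table",
    "assign_taxonomy",
    "TABLE_PREFERENCE",
]

#: multi-table resolution order: fungal mitochondrial first (mitoviruses are
#: thought to mainly infect fungal hosts), then invertebrate, then vertebrate
TABLE_PREFERENCE = (4, 5, 2)


@dataclass(frozen=True)
class Contig:
    contig_id: str
    seq: str
    source_run: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.contig_id!r} has an empty sequence")


@dataclass(frozen=True)
class OrfCall:
    """A located open reading frame on a contig under one genetic code.

    ``start``/``end`` are 0-based half-open forward-strand coordinates and
    include the terminal stop codon when ``has_terminal_stop``.  ``frame``
    is the reading-frame offset on the translated strand (0–2).
    """

    contig_id: str
    table_id: int
    strand: str
    frame: int
    start: int
    end: int
    has_terminal_stop: bool
    peptide: str
    used_alt_start: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span must be a whole number of codons")

    @property
    def aa_len(self) -> int:
        return len(self.peptide)

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}:{self.strand}{self.frame}:{self.start}-{self.end}"

    def coding_nt(self, contig: Contig, include_stop: bool = False) -> str:
        """The ORF's nucleotide sequence in reading orientation."""
        from .genetic_codes import reverse_complement

        if self.contig_id != contig.contig_id:
            raise ValueError(
                f"ORF belongs to {self.contig_id!r}, not {contig.contig_id!r}"
            )
        if not (0 <= self.start <= self.end <= len(contig.seq)):
            raise ValueError(f"ORF {self.orf_id} out of bounds for its contig")
        nt = contig.seq[self.start : self.end].upper().replace("U", "T")
        if self.strand == "-":
            nt = reverse_complement(nt)
        if self.has_terminal_stop and not include_stop:
            nt = nt[:-3]
        return nt


@dataclass(frozen=True)
class HitRecord:
    """One row of a BLAST/DIAMOND tabular (outfmt 6 style) hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    subject_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for hit {self.query_id}→{self.subject_id}")


def filter_contigs(contigs: Iterable[Contig], min_len_bp: int = 900) -> list[Contig]:
    """Keep contigs long enough to encode a mitoviral RdRp (≥ ``min_len_bp``)."""
    if min_len_bp < 1:
        raise ValueError("min_len_bp must be ≥ 1")
    return [c for c in contigs if len(c.seq) >= min_len_bp]


def find_orfs(
    contig: Contig,
    code: GeneticCode,
    min_aa: int = 300,
    require_start: bool = True,
    allow_alt_starts: bool = True,
) -> list[OrfCall]:
    """Find ORFs in all six translational contexts of a contig.

    Parameters
    ----------
    min_aa:
        Minimum peptide length in residues, excluding the terminal stop.
    require_start:
        If true (default) an ORF must begin at a start codon of the code;
        if false, stop-to-stop segments are reported from their first codon
        (sensitivity-analysis mode).
    allow_alt_starts:
        If true, the code's full honoured initiation set is used (for
        tables 2 and 5 this includes the NCBI alternative initiators);
        if false only ATG qualifies.

    Returns calls sorted by (strand, frame, start).  The initiator residue
    is reported as M whenever ``require_start`` holds, including for
    alternative initiators (initiator-tRNA behaviour).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be ≥ 1")
    enc_fwd = encode_sequence(contig.seq)
    L = enc_fwd.size
    aa_lut = code.aa_lut
    stop_lut = code.stop_lut()
    start_lut = code.start_lut(allow_alt_starts)
    calls: list[OrfCall] = []

    for strand in "+-":
        enc = enc_fwd if strand == "+" else np.where(enc_fwd == 4, 4, 3 - enc_fwd)[::-1]
        for frame in range(3):
            idx = codon_indices(enc, frame)
            m = idx.size
            if m == 0:
                continue
            stops = np.flatnonzero(stop_lut[idx])
            starts = np.flatnonzero(start_lut[idx]) if require_start else None
            seg_begin = 0
            for stop_pos in [*stops.tolist(), m]:
                truncated = stop_pos == m
                if truncated and seg_begin >= m:
                    break
                if require_start:
                    k = np.searchsorted(starts, seg_begin)
                    if k == starts.size or starts[k] >= stop_pos:
                        seg_begin = stop_pos + 1
                        continue
                    first = int(starts[k])
                else:
                    first = seg_begin
                aa_len = stop_pos - first
                if aa_len >= min_aa:
                    pep = aa_lut[idx[first:stop_pos]].tobytes().decode("ascii")
                    start_codon_is_atg = idx[first] == 14  # ATG = 0*16+3*4+2
                    if require_start:
                        pep = "M" + pep[1:]
                    lo = frame + 3 * first
                    hi = frame + 3 * (stop_pos + (0 if truncated else 1))
                    if strand == "-":
                        lo, hi = L - hi, L - lo
                    calls.append(
                        OrfCall(
                            contig_id=contig.contig_id,
                            table_id=code.table_id,
                            strand=strand,
                            frame=frame,
                            start=lo,
                            end=hi,
                            has_terminal_stop=not truncated,
                            peptide=pep,
                            used_alt_start=require_start and not start_codon_is_atg,
                        )
                    )
                seg_begin = stop_pos + 1

    calls.sort(key=lambda o: (o.strand, o.frame, o.start))
    return calls


def single_orf_filter(calls: Iterable[OrfCall]) -> list[OrfCall]:
    """Keep only (contig, table) groups containing exactly one ORF call.

    Contigs with two or more qualifying ORFs under a table are dropped
    entirely under that table — a mitovirus genome encodes a single RdRp
    ORF, so multi-ORF contigs are treated as non-mitoviral.
    """
    groups: dict[tuple[str, int], list[OrfCall]] = {}
    order: list[tuple[str, int]] = []
    for call in calls:
        key = (call.contig_id, call.table_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(call)
    return [groups[key][0] for key in order if len(groups[key]) == 1]


def resolve_table(calls_by_table: Mapping[int, OrfCall]) -> OrfCall:
    """Resolve one contig's per-table calls to a single ORF.

    The fungal mitochondrial table 4 wins when present; otherwise the
    deterministic preference order 4 > 5 > 2 applies.
    """
    if not calls_by_table:
        raise ValueError("no ORF calls to resolve")
    for tid in TABLE_PREFERENCE:
        if tid in calls_by_table:
            return calls_by_table[tid]
    # tables outside the documented preference order: lowest id wins
    return calls_by_table[min(calls_by_table)]


def assign_taxonomy(orf_id: str, hits: Sequence[HitRecord]) -> HitRecord | None:
    """Pick the top hit by E-value for final taxonomy assignment.

    Ties on E-value break by larger bitscore, then lexicographic
    subject_id.  Returns ``None`` when there are no hits.
    """
    relevant = [h for h in hits if h.query_id == orf_id]
    if not relevant:
        return None
    return min(relevant, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
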