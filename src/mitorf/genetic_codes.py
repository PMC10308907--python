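"""NCBI genetic codes and frame/strand-aware translation.

Mitoviruses are thought to be translated on mitochondrial ribosomes, which
decode UGA as tryptophan rather than as a stop.  This module represents the
four NCBI translation tables the pipeline needs — 1 (standard), 2 (vertebrate
mitochondrial), 4 (mold/protozoan, here "fungal", mitochondrial) and
5 (invertebrate mitochondrial) — loaded from a machine-readable data file so
the assignments can be diffed against an independent copy of the NCBI
specification.

The internal alphabet is DNA; RNA input is accepted and normalised U→T on
ingest (contigs are assembled from cDNA reads).  Codons containing N
translate to ``X`` and never match a start or stop set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "GeneticCode",
    "get_code",
    "translate",
    "reverse_complement",
    "SUPPORTED_TABLES",
    "CODONS",
]

SUPPORTED_TABLES = (1, 2, 4, 5)

#: the 64 DNA codons in lexicographic order (the fixed vector order used
#: throughout the package, e.g. for codon-usage vectors)
CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level encodings used by the vectorised translator
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case
for _b in b"Nn":
    _BASE_CODE[_b] = 4
for _b in b"Uu":
    _BASE_CODE[_b] = 3  # U → T


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table.

    Attributes
    ----------
    table_id:
        NCBI transl_table number (1, 2, 4 or 5).
    name:
        NCBI name of the table.
    codon_to_aa:
        Map from each of the 64 DNA triplets to a one-letter amino acid,
        with ``*`` for termination codons.
    ncbi_start_codons:
        The full set of initiation codons flagged in the NCBI specification
        for this table (shipped verbatim so it can be diffed against an
        independent transcription).
    start_codons:
        The initiation set honoured during ORF calling.  For tables 2 and 5
        this is the full NCBI set — mitochondrial initiation is famously
        promiscuous in vertebrates and invertebrates.  For tables 1 and 4
        only ATG is honoured: the fungal-mitochondrial alternative starts in
        the NCBI flags (TTA, CTG, ...) are poorly supported across fungi and
        would flood ORF calls with spurious upstream extensions.
    """

    table_id: int
    name: str
    codon_to_aa: dict[str, str]
    ncbi_start_codons: frozenset[str]
    start_codons: frozenset[str] = field(init=False)
    stop_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            raise ValueError("codon_to_aa must cover exactly the 64 DNA triplets")
        stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")
        starts = (
            self.ncbi_start_codons
            if self.table_id in (2, 5)
            else frozenset({"ATG"})
        )
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "start_codons", starts)

    # -- vectorised lookup tables (indexed by codon index 16a+4b+c; 64 = N) --

    @property
    def aa_lut(self) -> np.ndarray:
        return _luts(self.table_id)[0]

    def stop_lut(self) -> np.ndarray:
        return _luts(self.table_id)[1]

    def start_lut(self, alt_starts: bool) -> np.ndarray:
        return _luts(self.table_id)[2 if alt_starts else 3]


def _codon_index(codon: str) -> int:
    i = 0
    for b in codon:
        i = i * 4 + "ACGT".index(b)
    return i


@lru_cache(maxsize=None)
def _load_data() -> dict:
    with resources.files("mitorf.data").joinpath("genetic_codes.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def get_code(table_id: int) -> GeneticCode:
    """Return the :class:`GeneticCode` for an NCBI transl_table number.

    Raises
    ------
    ValueError
        If ``table_id`` is not one of the supported tables 1, 2, 4, 5.
    """
    if table_id not in SUPPORTED_TABLES:
        raise ValueError(
            f"unsupported translation table {table_id!r}; "
            f"supported tables are {', '.join(map(str, SUPPORTED_TABLES))}"
        )
    rec = _load_data()[str(table_id)]
    return GeneticCode(
        table_id=rec["id"],
        name=rec["name"],
        codon_to_aa=dict(rec["codon_to_aa"]),
        ncbi_start_codons=frozenset(rec["ncbi_start_codons"]),
    )


@lru_cache(maxsize=None)
def _luts(table_id: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(aa letters, is-stop, is-start-with-alt, is-ATG) per codon index, 65 slots."""
    code = get_code(table_id)
    aa = np.full(65, ord("X"), dtype=np.uint8)
    stop = np.zeros(65, dtype=bool)
    start_alt = np.zeros(65, dtype=bool)
    start_atg = np.zeros(65, dtype=bool)
    for codon in CODONS:
        i = _codon_index(codon)
        aa[i] = ord(code.codon_to_aa[codon])
        stop[i] = codon in code.stop_codons
        start_alt[i] = codon in code.start_codons
    start_atg[_codon_index("ATG")] = True
    return aa, stop, start_alt, start_atg


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as base codes (A,C,G,T → 0..3; N → 4).

    Raises ``ValueError`` identifying the position of the first character
    outside {A, C, G, T, U, N} (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    enc = _BASE_CODE[raw]
    bad = np.flatnonzero(enc == 255)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"invalid nucleotide {seq[pos]!r} at position {pos}; "
            "expected A, C, G, T, U or N"
        )
    return enc


def codon_indices(enc: np.ndarray, offset: int = 0) -> np.ndarray:
    """Codon index array (0..63; 64 where the triplet contains N).

    Successive complete triplets starting at ``offset``; a trailing
    incomplete triplet is ignored.
    """
    n = (enc.size - offset) // 3
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    tri = enc[offset : offset + 3 * n].reshape(n, 3).astype(np.int64)
    idx = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    idx[(tri == 4).any(axis=1)] = 64
    return idx


def translate(seq: str, code: GeneticCode, offset: int = 0, strand: str = "+") -> str:
    """Translate successive complete triplets of ``seq``.

    Parameters
    ----------
    seq:
        Nucleotide string over A, C, G, T, U, N (case-insensitive; U is
        normalised to T).
    code:
        Translation table to decode with.
    offset:
        Reading-frame offset, 0–2, applied on the translated strand.
    strand:
        ``"+"`` translates the sequence as given; ``"-"`` translates its
        reverse complement.

    Stops are rendered ``*``; any triplet containing N renders ``X``; a
    trailing incomplete triplet is ignored.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    enc = encode_sequence(seq)
    if strand == "-":
        enc = np.where(enc == 4, 4, 3 - enc)[::-1]
    idx = codon_indices(enc, offset)
    return code.aa_lut[idx].tobytes().decode("ascii")
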