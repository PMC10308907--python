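"""Synthetic mitovirus-like datasets with machine-readable ground truth.

Generates the statistical structure the analysis assumes, so every pipeline
stage is testable without downloads: contigs of ≥900 bp carrying a single
long RdRp-like ORF (≥300 codons) with a controlled number of in-frame UGA
(tryptophan-on-mitoribosomes) codons, codon usage sampled from a chosen
reference table, random strand placement, flanking UTRs, AT-content
steering, and edge truncation — plus decoy contigs guaranteed to contain no
qualifying ORF under any supported genetic code, reference CDS FASTA sets,
and a SAM read-mapping fixture.  A truth table records, per contig, the
planted coordinates, genetic code, UGA count, source usage table and
mapped-read count.

All randomness flows from one integer seed through a single NumPy
generator, so identical specs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_usage import CodonUsageTable, read_usage_table
from .genetic_codes import CODONS, GeneticCode, get_code, reverse_complement
from .orfs import Contig, find_orfs

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "sample_orf",
    "make_dataset",
    "builtin_usage_table",
    "BUILTIN_USAGE_TABLES",
]

#: shipped synthetic reference usage tables (constructed stand-ins, shaped
#: like compartment codon-usage tables: shared amino-acid composition,
#: divergent wobble preference, pairwise R² ≈ 0.57)
BUILTIN_USAGE_TABLES = (
    "synthetic_fungal_mito_like",
    "synthetic_fungal_nuclear_like",
)


def builtin_usage_table(name: str) -> CodonUsageTable:
    if name not in BUILTIN_USAGE_TABLES:
        raise ValueError(
            f"unknown built-in usage table {name!r}; available: {BUILTIN_USAGE_TABLES}"
        )
    with resources.as_file(
        resources.files("mitorf.data").joinpath(f"{name}.tsv")
    ) as path:
        return read_usage_table(path)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the discovered-cohort conditions: ORFs of 300–800
    codons (contigs comfortably ≥900 bp), 48% of viral contigs carrying at
    least one in-frame UGA, fungal-mitochondrial-like codon usage, mixed
    strands, a small edge-truncated fraction, and AT-rich composition.
    """

    n_viral: int = 200
    n_decoy: int = 200
    orf_len_aa: tuple[int, int] = (300, 800)
    frac_uga: float = 0.48
    uga_range: tuple[int, int] = (1, 6)
    n_uga: tuple[int, ...] | None = None  # explicit per-contig counts override
    source_usage: str = "synthetic_fungal_mito_like"
    utr_len: tuple[int, int] = (30, 150)
    at_target: float = 0.62
    frac_minus_strand: float = 0.5
    frac_edge_truncated: float = 0.1
    table_id: int = 4
    mean_mapped_reads: float = 30.0
    total_reads: int = 8_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_uga", "frac_minus_strand", "frac_edge_truncated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.orf_len_aa[0] < 300:
            raise ValueError("discoverable ORFs need ≥ 300 codons")
        if self.n_uga is not None and len(self.n_uga) != self.n_viral:
            raise ValueError("explicit n_uga must have one entry per viral contig")


@dataclass
class SyntheticDataset:
    contigs: list[Contig]
    truth: pd.DataFrame
    spec: SyntheticSpec

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write contigs.fasta, truth.tsv, reference CDS FASTAs and reads.sam."""
        from .io import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": out / "contigs.fasta",
            "truth": out / "truth.tsv",
            "sam": out / "reads.sam",
        }
        write_fasta(self.contigs, paths["contigs"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_sam_fixture(self, paths["sam"])
        for name in BUILTIN_USAGE_TABLES:
            p = out / f"ref_cds_{name}.fasta"
            cds = sample_reference_cds(
                builtin_usage_table(name), n_records=40, seed=self.spec.seed
            )
            write_fasta(
                [Contig(f"{name}_cds_{i:03d}", s) for i, s in enumerate(cds)], p
            )
            paths[f"ref_cds_{name}"] = p
        return paths


# stop codon planted at segment boundaries; terminates in every supported code
_UNIVERSAL_STOP = "TAA"
_MAX_REJECTIONS = 200


def _usage_probs(usage: CodonUsageTable, allowed: list[str]) -> np.ndarray:
    p = np.array([usage.freq(c) for c in allowed])
    if p.sum() <= 0:
        raise ValueError(
            f"usage table {usage.label!r} has no mass on the allowed codons"
        )
    return p / p.sum()


def sample_orf(
    len_aa: int,
    usage: CodonUsageTable,
    n_uga: int,
    code: GeneticCode,
    rng: np.random.Generator | int,
) -> str:
    """Sample one ORF nucleotide sequence (start codon … stop codon).

    The ORF begins with ATG, ends with a stop codon of ``code``, contains
    exactly ``n_uga`` in-frame TGA codons at positions sampled uniformly
    among the body slots, and no other in-frame stop of ``code``; remaining
    body codons are drawn from ``usage`` restricted to codons that are
    sense in ``code`` (TGA excluded so the planted count stays exact).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_body = len_aa - 1  # slots after the initiator
    if n_uga < 0 or n_uga > n_body:
        raise ValueError(f"cannot place {n_uga} UGA codons in {n_body} body slots")
    allowed = [
        c
        for c in CODONS
        if c not in code.stop_codons and c != "TGA" and c not in ("TAA", "TAG")
    ]
    probs = _usage_probs(usage, allowed)
    body = list(rng.choice(allowed, size=n_body, p=probs))
    if n_uga:
        slots = rng.choice(n_body, size=n_uga, replace=False)
        for s in slots:
            body[s] = "TGA"
    return "ATG" + "".join(body) + _UNIVERSAL_STOP


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _verified_viral_contig(
    spec: SyntheticSpec, rng: np.random.Generator, usage, code, len_aa, n_uga
) -> tuple[str, dict] | None:
    """One viral contig candidate plus its truth row; None if verification fails.

    Verification re-runs the discovery stage and accepts only contigs whose
    single table-4 call lands exactly on the planted coordinates — spurious
    long ORFs in shifted frames or on the opposite strand (rare at this AT
    content) trigger regeneration.
    """
    orf = sample_orf(len_aa, usage, n_uga, code, rng)
    utr5_len = int(rng.integers(*spec.utr_len))
    utr3_len = int(rng.integers(*spec.utr_len))
    truncated = rng.random() < spec.frac_edge_truncated
    minus = rng.random() < spec.frac_minus_strand
    # steer overall AT toward the target by biasing UTR composition
    utr_at = min(0.9, max(0.1, spec.at_target + (spec.at_target - 0.578)))
    utr5 = _random_seq(rng, utr5_len, utr_at)
    # in-frame stop immediately 5' of the start pins the segment boundary
    if utr5_len >= 3:
        utr5 = utr5[:-3] + _UNIVERSAL_STOP
    else:
        utr5 = _UNIVERSAL_STOP
        utr5_len = 3
    if truncated:
        orf = orf[:-3]  # drop terminal stop; contig ends at the ORF edge
        utr3 = ""
    else:
        utr3 = _random_seq(rng, utr3_len, utr_at)
    fwd = utr5 + orf + utr3
    start, end = utr5_len, utr5_len + len(orf)
    seq = reverse_complement(fwd) if minus else fwd
    if minus:
        start, end = len(fwd) - end, len(fwd) - start
    contig_seq = seq
    frame = (len(contig_seq) - end) % 3 if minus else start % 3

    # verification: exactly one qualifying table-4 call, at the planted spot
    probe = Contig("probe", contig_seq)
    calls = find_orfs(probe, code, min_aa=300)
    if len(calls) != 1:
        return None
    c = calls[0]
    if (c.start, c.end, c.strand, c.frame) != (start, end, "-" if minus else "+", frame):
        return None
    if c.has_terminal_stop == truncated:
        return None
    truth = {
        "table_id": code.table_id,
        "strand": "-" if minus else "+",
        "frame": frame,
        "start": start,
        "end": end,
        "n_uga": n_uga,
        "len_aa": len_aa,
        "has_terminal_stop": not truncated,
        "source_usage": usage.label,
        "is_decoy": False,
    }
    return contig_seq, truth


def _decoy_contig(
    spec: SyntheticSpec, rng: np.random.Generator, length: int
) -> str | None:
    """Random contig with no ≥300-codon ORF under any supported table."""
    seq = _random_seq(rng, length, spec.at_target)
    contig = Contig("probe", seq)
    for tid in (1, 2, 4, 5):
        if find_orfs(contig, get_code(tid), min_aa=300):
            return None
    return seq


def _uga_assignment(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    if spec.n_uga is not None:
        return list(spec.n_uga)
    n_with = round(spec.frac_uga * spec.n_viral)
    counts = [int(rng.integers(spec.uga_range[0], spec.uga_range[1] + 1))
              for _ in range(n_with)]
    counts += [0] * (spec.n_viral - n_with)
    perm = rng.permutation(spec.n_viral)
    return [counts[i] for i in perm]


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full synthetic cohort: viral contigs, decoys, truth table.

    Deterministic under ``spec.seed``.  Raises if rejection sampling cannot
    satisfy the constraints within an iteration cap (loosen ``at_target``
    or shorten ORFs in that case).
    """
    rng = np.random.default_rng(spec.seed)
    usage = builtin_usage_table(spec.source_usage)
    code = get_code(spec.table_id)
    uga_counts = _uga_assignment(spec, rng)

    contigs: list[Contig] = []
    rows: list[dict] = []
    for i in range(spec.n_viral):
        len_aa = int(rng.integers(spec.orf_len_aa[0], spec.orf_len_aa[1] + 1))
        for attempt in range(_MAX_REJECTIONS):
            out = _verified_viral_contig(spec, rng, usage, code, len_aa, uga_counts[i])
            if out is not None:
                break
        else:
            raise RuntimeError(
                f"viral contig {i}: rejection sampling exceeded "
                f"{_MAX_REJECTIONS} attempts; consider shorter ORFs or a "
                "more AT-rich usage table"
            )
        seq, truth = out
        cid = f"synthcontig_{i:04d}"
        contigs.append(Contig(cid, seq, source_run="SYNTH000001"))
        rows.append({"contig_id": cid, **truth,
                     "mapped_reads": int(rng.poisson(spec.mean_mapped_reads))})

    for i in range(spec.n_decoy):
        length = int(rng.integers(900, 3001))
        for attempt in range(_MAX_REJECTIONS):
            seq = _decoy_contig(spec, rng, length)
            if seq is not None:
                break
        else:
            raise RuntimeError(
                f"decoy {i}: rejection sampling exceeded {_MAX_REJECTIONS} "
                "attempts; consider shorter decoys or higher at_target"
            )
        cid = f"synthdecoy_{i:04d}"
        contigs.append(Contig(cid, seq, source_run="SYNTH000001"))
        rows.append({
            "contig_id": cid, "table_id": 0, "strand": ".", "frame": -1,
            "start": -1, "end": -1, "n_uga": 0, "len_aa": 0,
            "has_terminal_stop": False, "source_usage": "", "is_decoy": True,
            "mapped_reads": int(rng.poisson(spec.mean_mapped_reads / 10)),
        })

    truth = pd.DataFrame(rows)
    return SyntheticDataset(contigs=contigs, truth=truth, spec=spec)


def sample_reference_cds(
    usage: CodonUsageTable,
    n_records: int = 40,
    len_range: tuple[int, int] = (200, 500),
    seed: int = 0,
) -> list[str]:
    """Reference CDS set drawn from a usage table (standard-code sense codons)."""
    rng = np.random.default_rng(seed)
    sense = [c for c in CODONS if c not in ("TAA", "TAG", "TGA")]
    probs = _usage_probs(usage, sense)
    out = []
    for _ in range(n_records):
        n = int(rng.integers(*len_range))
        body = "".join(rng.choice(sense, size=n, p=probs))
        out.append("ATG" + body + "TAA")
    return out


def write_sam_fixture(dataset: SyntheticDataset, path: str | Path) -> None:
    """Plain-text SAM with ``mapped_reads`` primary records per viral contig.

    Reads are 50-mer substrings of their contig; unmapped records pad the
    file so the total equals ``spec.total_reads`` when small enough,
    otherwise total = mapped + a fixed unmapped pad of 10%.
    """
    rng = np.random.default_rng(dataset.spec.seed + 1)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    by_id = {c.contig_id: c for c in dataset.contigs}
    mapped_rows = dataset.truth[~dataset.truth.is_decoy]
    for cid in mapped_rows.contig_id:
        lines.append(f"@SQ\tSN:{cid}\tLN:{len(by_id[cid].seq)}")
    qname = 0
    n_mapped = 0
    for _, row in mapped_rows.iterrows():
        seq = by_id[row.contig_id].seq
        for _ in range(int(row.mapped_reads)):
            pos = int(rng.integers(0, max(1, len(seq) - 50)))
            read = seq[pos : pos + 50]
            lines.append(
                f"read_{qname:06d}\t0\t{row.contig_id}\t{pos + 1}\t42\t"
                f"{len(read)}M\t*\t0\t0\t{read}\t{'I' * len(read)}"
            )
            qname += 1
            n_mapped += 1
    n_unmapped = max(0, dataset.spec.total_reads - n_mapped)
    if n_unmapped > 20_000:  # keep fixtures small; scale denominator instead
        n_unmapped = max(1, n_mapped // 10)
    for _ in range(n_unmapped):
        read = _random_seq(rng, 50, 0.5)
        lines.append(
            f"read_{qname:06d}\t4\t*\t0\t0\t*\t*\t0\t0\t{read}\t{'I' * 50}"
        )
        qname += 1
    Path(path).write_text("\n".join(lines) + "\n")
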