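"""End-to-end orchestration: discover → resolve → readthrough → codon usage
→ composition → abundance.

Mirrors the discovery pipeline's stage order: contigs are length-filtered,
scanned for ORFs under each configured mitochondrial codon table, reduced to
single-ORF contigs per table, and resolved across tables with a
fungal-mitochondrial preference; the resolved ORFs are then analysed for
UGA readthrough, codon-usage correlation against reference compartments,
AT content, and (when a SAM file is supplied) RPKM abundance.

Every report is a TSV with a fixed column order and deterministic row
order, so two runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_usage import CodonUsageTable, correlate_all, read_usage_table
from .genetic_codes import get_code
from .io import read_fasta, read_hit_table, write_orf_table, write_peptides
from .orfs import (
    Contig,
    OrfCall,
    assign_taxonomy,
    filter_contigs,
    find_orfs,
    resolve_table,
    single_orf_filter,
)
from .readthrough import analyze_orf, summarize_readthrough
from .stats import at_content, count_mapped, rpkm
from .synthetic import BUILTIN_USAGE_TABLES, builtin_usage_table

logger = logging.getLogger("mitorf")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "discover_orfs"]

SCHEMA_VERSION = "mitorf-report-v1"


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds; defaults are the discovery pipeline's settings."""

    min_contig_bp: int = 900
    min_orf_aa: int = 300
    tables: tuple[int, ...] = (2, 4, 5)
    table_preference: tuple[int, ...] = (4, 5, 2)
    require_start: bool = True
    alt_start_tables: tuple[int, ...] = (2, 5)
    codon_subset: str = "all64"
    reference_tables: tuple[str, ...] = BUILTIN_USAGE_TABLES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tables", "table_preference", "alt_start_tables", "reference_tables"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    orfs: list[OrfCall]
    orf_table: pd.DataFrame
    readthrough: pd.DataFrame
    readthrough_summary: pd.DataFrame
    correlation: pd.DataFrame | None
    composition: pd.DataFrame
    abundance: pd.DataFrame | None
    taxonomy: pd.DataFrame | None


def discover_orfs(
    contigs: list[Contig], config: PipelineConfig
) -> dict[str, OrfCall]:
    """Length filter → six-frame ORF search per table → single-ORF filter →
    cross-table resolution.  Returns the resolved call per contig."""
    kept = filter_contigs(contigs, config.min_contig_bp)
    per_table: dict[int, dict[str, OrfCall]] = {}
    for tid in config.tables:
        code = get_code(tid)
        calls: list[OrfCall] = []
        for contig in kept:
            calls.extend(
                find_orfs(
                    contig,
                    code,
                    min_aa=config.min_orf_aa,
                    require_start=config.require_start,
                    allow_alt_starts=tid in config.alt_start_tables,
                )
            )
        surviving = single_orf_filter(calls)
        per_table[tid] = {c.contig_id: c for c in surviving}
    resolved: dict[str, OrfCall] = {}
    for contig in kept:
        by_table = {
            tid: per_table[tid][contig.contig_id]
            for tid in config.tables
            if contig.contig_id in per_table[tid]
        }
        if by_table:
            resolved[contig.contig_id] = resolve_table(by_table)
    return resolved


def _load_reference(name_or_path: str) -> CodonUsageTable:
    if name_or_path in BUILTIN_USAGE_TABLES:
        return builtin_usage_table(name_or_path)
    return read_usage_table(name_or_path)


def run_pipeline(
    config: PipelineConfig,
    contigs_fasta: str | Path,
    out_dir: str | Path,
    hits_path: str | Path | None = None,
    sam_path: str | Path | None = None,
) -> PipelineResult:
    """Run every stage and write the report bundle into ``out_dir``.

    Reports: orfs.tsv, peptides.fasta, readthrough.tsv, readthrough_summary.tsv,
    correlation_matrix.tsv, composition.tsv, abundance.tsv (when a SAM is
    given), taxonomy.tsv (when a hit table is given) and run_log.txt.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = read_fasta(contigs_fasta)
    by_id = {c.contig_id: c for c in contigs}
    logger.info("read %d contigs from %s", len(contigs), contigs_fasta)

    resolved = discover_orfs(contigs, config)
    calls = [resolved[cid] for cid in sorted(resolved)]
    logger.info("resolved %d single-ORF contigs", len(calls))
    write_orf_table(calls, out / "orfs.tsv")
    write_peptides(calls, out / "peptides.fasta")

    reports = [analyze_orf(c, by_id[c.contig_id]) for c in calls]
    rt = pd.DataFrame(
        [
            {
                "orf_id": r.orf_id,
                "table_id": r.table_id,
                "n_uga": r.n_uga,
                "len_mito_aa": r.len_mito_aa,
                "len_standard_aa": r.len_standard_aa,
                "requires_mito": r.requires_mito,
            }
            for r in reports
        ],
        columns=[
            "orf_id", "table_id", "n_uga", "len_mito_aa",
            "len_standard_aa", "requires_mito",
        ],
    )
    rt.to_csv(out / "readthrough.tsv", sep="\t", index=False)
    rt_summary = summarize_readthrough(reports)
    rt_summary.to_csv(out / "readthrough_summary.tsv", sep="\t", index=False)

    correlation = None
    if config.reference_tables:
        refs = [_load_reference(r) for r in config.reference_tables]
        pairs = [
            (c.orf_id, c.coding_nt(by_id[c.contig_id], include_stop=False))
            for c in calls
        ]
        if pairs:
            matrix = correlate_all(pairs, refs, codon_subset=config.codon_subset)
            matrix.write_tsv(out / "correlation_matrix.tsv")
            correlation = matrix.to_frame()
        else:
            correlation = pd.DataFrame(
                columns=[r.label for r in refs] + ["best_match", "tie"]
            )
            correlation.to_csv(out / "correlation_matrix.tsv", sep="\t",
                               index_label="orf_id")

    comp = pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "length_bp": len(by_id[c.contig_id].seq),
                "at_content": at_content(by_id[c.contig_id].seq),
                "aa_len": c.aa_len,
            }
            for c in calls
        ],
        columns=["contig_id", "length_bp", "at_content", "aa_len"],
    )
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)

    abundance = None
    if sam_path is not None:
        counts, total = count_mapped(sam_path)
        abundance = pd.DataFrame(
            [
                {
                    "contig_id": cid,
                    "mapped_reads": n,
                    "contig_len_bp": len(by_id[cid].seq),
                    "total_reads": total,
                    "rpkm": rpkm(n, len(by_id[cid].seq), total),
                }
                for cid, n in sorted(counts.items())
                if cid in by_id
            ],
            columns=["contig_id", "mapped_reads", "contig_len_bp",
                     "total_reads", "rpkm"],
        )
        abundance.to_csv(out / "abundance.tsv", sep="\t", index=False)

    taxonomy = None
    if hits_path is not None:
        hits = read_hit_table(hits_path)
        tax_rows = []
        for c in calls:
            top = assign_taxonomy(c.orf_id, hits)
            tax_rows.append(
                {
                    "orf_id": c.orf_id,
                    "subject_id": top.subject_id if top else "",
                    "evalue": top.evalue if top else "",
                    "bitscore": top.bitscore if top else "",
                    "subject_taxon": (top.subject_taxon or "") if top else "",
                }
            )
        taxonomy = pd.DataFrame(
            tax_rows,
            columns=["orf_id", "subject_id", "evalue", "bitscore", "subject_taxon"],
        )
        taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)

    (out / "run_log.txt").write_text(
        f"schema\t{SCHEMA_VERSION}\n"
        f"version\t{__version__}\n"
        f"config\t{config}\n"
        f"n_contigs\t{len(contigs)}\n"
        f"n_resolved_orfs\t{len(calls)}\n"
    )
    return PipelineResult(
        orfs=calls,
        orf_table=pd.read_csv(out / "orfs.tsv", sep="\t"),
        readthrough=rt,
        readthrough_summary=rt_summary,
        correlation=correlation,
        composition=comp,
        abundance=abundance,
        taxonomy=taxonomy,
    )
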