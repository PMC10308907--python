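# Methods

This note records the models, conventions and design choices behind
`mitorf`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, what the synthetic data do and do not emulate, and
where the design was genuinely open.

## Genetic codes and translation

Four NCBI translation tables are supported: 1 (standard), 2 (vertebrate
mitochondrial), 4 (mold/protozoan — "fungal" — mitochondrial) and
5 (invertebrate mitochondrial). The 64 codon assignments and the NCBI
initiation flags are shipped as data (`data/genetic_codes.json`), not code,
so they can be diffed against any independent transcription of the NCBI
specification; the test suite diffs them against Biopython's copy. The
discriminating assignments are UGA→Trp in 2/4/5, AGA/AGG as stops in 2 and
Ser in 5, and AUA→Met in 2/5.

Initiation policy: the NCBI flags list promiscuous start sets for every
table (even table 1 flags TTG/CTG). During ORF calling we honour the full
NCBI set only for tables 2 and 5, where alternative mitochondrial
initiators are biologically widespread; tables 1 and 4 honour ATG only.
The full NCBI sets remain available on the `GeneticCode` object
(`ncbi_start_codons`), and `allow_alt_starts=False` restricts any table to
ATG. Alternative initiators are decoded as Met at position 1
(initiator-tRNA behaviour), and the reported peptide excludes the terminal
stop.

The internal alphabet is DNA; RNA input is normalised U→T on ingest
(contigs are assembled from cDNA). Codons containing N translate to X and
never match start or stop sets — ambiguity never nucleates or terminates an
ORF. Translation is vectorised (codon-index lookup tables over NumPy byte
arrays), which is what makes the large oracle-equivalence checks cheap.

## ORF discovery

Semantics follow NCBI OrfFinder: within each stop-bounded segment of each
of the six translational contexts, the ORF runs from the *first* qualifying
start codon to the next in-frame stop; nested ORFs in the same segment are
not reported. This makes the single-ORF-per-contig filter meaningful.
ORFs truncated by the contig edge (no in-frame stop before the end) are
retained and flagged `has_terminal_stop=False`; real assemblies contain
such fragments, and downstream stages must see them. A stop-to-stop mode
(`require_start=False`) exists for sensitivity analyses but is not the
default.

Coordinates are 0-based, half-open, always on the forward strand, with a
strand flag; the span includes the terminal stop codon when present, and
the peptide length is (end − start)/3 − 1 in that case. The 300-residue
threshold counts peptide residues excluding the terminal stop. The
single-ORF filter is applied per (contig, table) pair: a contig with two
qualifying ORFs under table 4 contributes nothing under table 4 but may
still be called under another table. Cross-table resolution prefers table
4, then 5, then 2 — mitoviruses are thought to mainly infect fungal hosts.

Correctness is established against an independent exhaustive oracle that
enumerates every (start, next-stop) codon pair per frame and keeps the
earliest start per stop; implementation and oracle agree exactly on tens of
thousands of random contigs across all four tables, both start policies and
both strands.

## UGA readthrough

For each resolved ORF we count in-frame TGA codons strictly inside the
coding region (terminal stop excluded — the count concerns tryptophans in
the product) and compute the dual decoding lengths: the mitochondrial
length is the called peptide length; the cytosolic length is the number of
residues preceding the first standard-code stop (TAA/TAG/TGA) scanning the
same frame from the same start. For table-4 ORFs these two lengths differ
exactly when n(UGA) ≥ 1. For tables 2/5 the cytosolic stop set is the
standard-code set only (AGA/AGG, though stops in table 2, are Arg to a
cytosolic ribosome); the stop set is configurable. `requires_mito` is
defined as n(UGA) ≥ 1.

## Codon usage

Codon usage vectors are global codon fractions — counts over all complete
codons divided by the total — not per-amino-acid RSCU (an RSCU transform is
provided for sensitivity analysis). The default comparison uses all 64
codons with the query ORF's terminal stop excluded: stop identity differs
across genetic codes, and cross-table comparability requires counting raw
triplets; a 61-sense-codon mode is available. Similarity is Pearson's R²
(via `scipy.stats.pearsonr`), which is scale-invariant in the counts; a
zero-variance vector raises rather than silently returning 0. Best-match
assignment is the argmax over reference columns, with ties (ΔR² < 1e-12)
resolved by the fixed reference order and flagged. The exported matrix
carries a row order from average-linkage hierarchical clustering on the
rows' R² profiles — presentation only, mirroring heatmap row clustering.

The TSV reader accepts this package's codon/count/frequency layout and
HIVE-style per-1000 columns (renormalised on read).

## Composition, group tests, abundance

AT content is (A+T+U)/length with N in the denominator only. The
Mann–Whitney U statistic is computed with midranks; the p-value uses the
exact U null distribution when there are no ties and n·m ≤ 400, a complete
enumeration of pooled-sample splits when ties are present and
C(n+m, n) ≤ 200,000, and the normal approximation with tie and continuity
correction otherwise. The reported U is for the first sample, so
0 ≤ U ≤ n·m. RPKM is mapped reads / ((length/1000) × (total reads/10⁶)),
with the *total* read count of the run (mapped + unmapped) as the default
denominator; a mapped-only denominator exists behind a flag. SAM counting
uses primary alignments only by default (secondary/supplementary excluded;
`include_secondary=True` counts every aligned record), since the upstream
mapping policy is deliberately quality-agnostic.

## Synthetic data: what it emulates, and what it does not

The generator plants, per viral contig: a single ORF of 300–800 codons
(uniform), codons drawn from a chosen reference usage table restricted to
sense codons, exactly k in-frame TGA codons at uniformly chosen body slots,
an ATG initiator, a terminal stop, flanking UTRs of 30–150 bp, minus-strand
placement for half the cohort, edge truncation (no terminal stop, no 3′
UTR) for 10%, and AT-rich composition (target 0.62, steered through UTR
base composition; the mito-like usage table itself yields ≈0.58 coding AT).
By default 48% of viral contigs receive k ≥ 1 (k uniform on 1–6) — the
cohort fraction of UGA-containing ORFs observed in newly discovered
mitoviruses; a 55% setting emulates the previously reported reference
cohort. An in-frame TAA is written immediately 5′ of the planted start so
the enclosing stop-bounded segment begins exactly at the start codon, and
each emitted contig is verified by re-running the ORF finder: a candidate
is regenerated if the planted ORF is not recovered as the unique table-4
call at the planted coordinates (spurious long ORFs in shifted frames are
rare at this AT content, so rejections are infrequent). Decoys are
length-matched random sequences rejection-sampled until no ≥300-codon ORF
exists under any of the four tables — absence is provable by the oracle
scanner, and tests verify it that way.

The two shipped reference usage tables are *constructed* stand-ins (file
names and labels say `synthetic_`): both share one globular-protein
amino-acid composition, and they diverge in wobble-position preference
(strongly A/T-ending for the mitochondrial-like table, mildly C/G-ending
for the nuclear-like one), giving pairwise R² ≈ 0.57 — inside the 0.5–0.7
band that makes compartment-recovery tests a meaningful margin rather than
a trivial separation. Real NCBI- or HIVE-derived tables can be supplied as
TSVs anywhere a built-in name is accepted.

What the generator does **not** emulate: sequencing error, assembly
artefacts (chimeras, collapsed repeats), realistic length/abundance correlation
structure, phylogenetic autocorrelation between contigs, and homology — the
decoys are random sequence, not diverged non-mitoviral genes. Passing the
recovery tests therefore demonstrates the pipeline's correctness on its own
declared semantics, not discovery sensitivity on real SRA assemblies; the
headline counts of any real survey (hundreds of novel genomes) depend on
cloud-scale search and homology databases outside this package's scope.
The SAM fixture contains well-formed primary alignments and unmapped
padding reads only — enough to pin the counting semantics, not a realistic
error model.

## Problem sizes and numerical choices

The oracle-equivalence check runs 10,000 contigs of 120–3,000 bp in three
base compositions (GC-rich, uniform, AT-rich) through all four tables and
both start policies (80,000 comparisons, ~1.5 min); recovery cohorts use
200 viral + 200 decoy contigs; codon-usage recovery uses 200 replicates of
300 codons, the smallest ORF length the discovery stage accepts and hence
the hardest case for compartment assignment. Random draws all flow from
single seeded NumPy generators; dataset generation is byte-reproducible
under a fixed spec. Pearson R² agreement with the closed-form sum formula
is held to 1e-12; Mann–Whitney exact agreement with brute-force
enumeration to 1e-12. Best-match ties below 1e-12 are treated as exact
ties. The iteration cap on rejection sampling is 200 per record; hitting
it raises with advice rather than silently degrading.

## Known limitations

- Only NCBI tables 1/2/4/5 are shipped; other mitochondrial codes (e.g.
  yeast mitochondrial table 3, with CUN→Thr) are out of scope.
- The single-ORF filter is per (contig, table); a joint-across-tables
  variant would drop slightly more contigs and is not implemented.
- Codon-usage assignment is a nearest-reference classifier; it does not
  model within-compartment heterogeneity or provide calibrated
  uncertainty.
- `requires_mito` is a sequence-level statement about full-length product
  feasibility, not a measurement of readthrough efficiency.
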