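# Methods

This note documents the models and procedures implemented in `lncflow`,
the defaults that matter, the numerical conventions, and what the synthetic
data do and do not establish.

## Coordinates and formats

All intervals are held 0-based half-open internally; GTF input/output
(1-based, closed) converts at the boundary, and BED is consumed natively.
GTF lines are parsed with gffutils' single-line parser inside our own loop
so malformed lines are reported with their line number. Interval queries
(gene/mRNA/TE overlap, flank proximity) run on interval trees and are
required — and tested — to agree exactly with a linear scan.

BLAST tabular (12-column) hits are merged per (query, subject) pair before
any downstream use: query coverage is 100 × (union of query-aligned HSP
spans) / query length, while identity, E-value and bitscore come from the
best-bitscore HSP. The union is the conservative reading of "coverage":
counting overlapping HSPs twice would inflate it.

## Identification cascade

Filters run in a fixed order and the per-transcript trace records the
*first* rule that removed a model:

1. **strand** — models with strand "." carry no orientation information and
   cannot be classified; removed.
2. **proximity** (flank 500 bp) — single-exon models near a same-strand
   annotated mRNA are likely fragments of that gene's transcription unit.
   Distance is measured span-to-span; overlap counts as distance 0.
3. **sense overlap** — ≥ 1 exonic bp shared with a same-strand annotated
   mRNA exon contaminates the coding annotation; removed. Antisense
   overlaps are retained deliberately: they are the lncNAT candidates.
4. **expression / length** — max FPKM across samples below 0.5 (2.0 for
   single-exon models, which demand stronger support) *or* length < 200 bp.
   The disjunctive reading is forced by the lncRNA definition itself
   (> 200 nt): a conjunctive reading would admit 100-bp models. Expression
   is keyed by the assembler locus id (gene-level FPKM, the Cuffdiff-style
   convention); per-sample maximum is the thresholded statistic.
5. **coding potential** — score > 0 removes the model. Scores are normally
   supplied externally; the built-in surrogate returns +1 iff the longest
   forward-frame ORF (ATG through stop) is ≥ 300 nt, else −1. It is a
   deliberately simple, deterministic stand-in exposing the same contract.
6. **protein domain** — membership in a supplied domain-hit list.

Classification uses genomic-span (not exon-level) overlap: a survivor whose
span overlaps a protein-coding gene on the opposite strand is a lncNAT;
everything else is a lincRNA. Span-level overlap matches the natural
antisense transcript concept (intronic antisense pairs still interact);
exon-level overlap is the right granularity only for the sense-contamination
filter. Because filter 3 ran first, no survivor can overlap genes on both
strands at the exon level, and mixed-class loci are impossible by
construction — `merge_loci` treats one as a hard error.

Locus merging is transitive single-linkage on ≥ 1 bp span overlap within a
(chromosome, strand) pair, implemented as a start-sorted sweep (the union of
a connected component of intervals is contiguous, so joining each interval
that starts before the running max end equals the full transitive closure).
Tests verify it against an independent graph-components oracle.

## Descriptive properties

A/U fraction excludes N bases from the denominator. TE overlap uses the
locus genomic span, strand-agnostic, with the ≥ 10 bp criterion; an
exon-level assessment is obtained by passing exon intervals instead of
spans to the same routine. Percentages print to one decimal, rounded
half away from zero, matching how such tables are conventionally printed;
the A/U *ranking* across classes is always computed from the data, never
asserted. Mean (not median) transcript length is reported.

## Weighted coexpression network

Expression is log2(FPKM + 1)-transformed before correlation (raw mode
available); Pearson correlation defines similarity. The network is unsigned
by default, A = |r|^β (signed variant ((1+r)/2)^β via `signed=True`).
β defaults to the smallest power in 1..20 whose scale-free topology fit
reaches R² ≥ 0.8 — the R² of the linear fit of log10 p(k) on log10 k over
10 connectivity bins — falling back to the max-R² candidate; it can also be
set directly. The plain (unsigned-slope) R² is used so that an R² target of
0 degenerates cleanly to β = 1.

Topological overlap follows Zhang & Horvath (2005):
TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), diagonal 1.
Modules come from average-linkage hierarchical clustering of 1 − TOM with a
**static** cut at height 0.995 and a minimum module size of 30; smaller
clusters are labelled grey (unassigned) and modules are named by the
conventional size-ranked colour palette. A static cut is simpler and fully
deterministic; it will not split nested modules the way dynamic tree cut
can, which is an accepted limitation here.

The module eigengene is the first right-singular vector (over samples) of
the per-gene standardized module submatrix, sign-oriented to correlate
non-negatively with the module's mean standardized profile. Module–trait
association is Pearson r with the two-sided p from t = r√((n−2)/(1−r²)) on
n − 2 df; gene significance is |r(gene, trait)|, paired with module
membership |r(gene, eigengene)| for scatter output. Edges with TOM ≥ 0.08
are exported once per unordered pair with node-type annotations
(lncRNA / lipid-gene / other) in a Cytoscape-compatible TSV.

## Conservation

Two distinct sets are computed and never conflated:

- the **conserved** call requires a hit passing all three strict cutoffs
  (E-value < 1e-5, coverage > 40%, identity > 50%; all boundaries strict);
- the **coverage level** bins the broader homolog set — every hit passing
  the E-value cutoff alone — as [20,40)→1, [40,60)→2, [60,80)→3,
  [80,100]→4, below 20% unlevelled. Bins are left-closed/right-open with
  level 4 closed at 100 (the printed ranges overlap at their boundaries, so
  a convention is required; left-closed keeps the bins a partition).

Synteny: each lncRNA's 10 nearest protein-coding genes per side (by midpoint
distance, truncated at chromosome ends; a gene overlapping the locus ranks
nearest on its midpoint's side) are compared with the flanks of its top-5
BLAST hit loci (bitscore rank, ties by E-value then subject id) through a
protein-level best-hit ortholog map (E < 1e-5, ≤ 5 subjects per query,
mirroring max_target_seqs < 6; reciprocal-best mode available). The locus is
syntenically conserved when at least one side-matched (upstream↔upstream or
downstream↔downstream) flanking ortholog pair is shared; an
orientation-agnostic mode handles inverted blocks. Verdicts are invariant
under whole-chromosome coordinate translation of either genome (tested).

The level-vs-expression profile reports per-level max-FPKM distributions and
the Spearman ρ between level and expression; ρ is reported, never asserted,
and all-tied inputs yield 0 rather than NaN.

## qPCR

Per replicate, ΔCt = Ct_target − mean Ct_reference within the condition;
ΔΔCt = mean ΔCt_treatment − mean ΔCt_baseline; fold = 2^−ΔΔCt. Significance
is a two-sided two-sample t-test on the replicate ΔCt sets, Welch by default
(pooled-variance mode for the strict textbook form). Per-condition mean
reference normalization is the default because replicate pairing across
plates is rarely recorded; a paired mode exists.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *downstream products* of a two-subgenome seed
transcriptome study: chromosomes A01.., C01.. with evenly spaced two-exon
protein-coding genes; assembled transcripts planting one unambiguous case
per identification rule plus lincRNA/lncNAT survivors and isoform pairs;
sequences with controlled A/U content (0.60 for lncRNAs vs 0.45 for mRNAs)
and controlled ORF presence; TE intervals; a 12-sample expression matrix
with three planted 40-gene modules (within-module r = 0.8) of which one
follows a sigmoidal oil-accumulation curve over days after flowering
(low to ~20 DAF, steep rise 20–35 DAF); homology tables with mid-bin
coverages (30/50/70/90%) plus identity-, E-value- and no-hit failure cases;
synteny blocks with and without shared flanking orthologs; and triplicate
Ct tables with planted ΔΔCt effects (−3, +1.5, 0) under N(0, 0.1) noise.

Deliberate design choices:

- **Separation margins.** Planted cases sit clear of every threshold:
  400 vs 600 bp around the 500 bp flank rule, FPKM 0.4/1.5 vs 5 around the
  0.5/2 cutoffs, mid-bin conservation coverages. Boundary behaviour is
  exercised by dedicated boundary tests, not by the planted fixtures.
- **Orthogonal module seeds.** The three module seed profiles are
  Gram-Schmidt-orthogonalized (trait-linked seed first). With only 12
  samples, unconstrained random seed profiles can correlate by chance,
  blurring the planted partition; orthogonalization makes "three modules"
  true by construction rather than by luck.
- **Expression scale.** Log-scale gene profiles x = clip(4 + 1.5z, 0, ∞)
  are emitted as FPKM = 2^x − 1, so the analysis-side log2(FPKM+1)
  transform recovers the planted correlation structure exactly.

What passing on these data does **not** show: robustness to assembly
artefacts (fragmented or chimeric models), to FPKM estimation noise, to
overlapping filter interactions (real models can violate several rules at
once; the trace then reports only the first), to non-Gaussian expression
noise or batch structure, or to synteny erosion by local rearrangement.
The generator makes the logic testable; it is not a realism benchmark.

## Problem sizes and tolerances

Defaults keep every stage small and fast: ~40 planted transcripts over four
chromosomes for identification; 120 genes × 12 samples for the network
(TOM oracle comparisons at n ≤ 50, agreement required within 1e-12);
15 conservation queries and 15 synteny blocks; 1000 Monte-Carlo draws for
qPCR fold recovery. The whole test suite and the acceptance script each run
in well under a minute on one CPU. Numerical conventions: correlations are
clipped to [−1, 1] before the t transform; |r| = 1 maps to p = 0; eigengene
sign ties (flat mean profile) resolve toward a non-negative sum; zero-
variance genes are an error at similarity time, listed by id, rather than a
silent NaN.

## Known limitations

- The static tree cut cannot separate modules whose between-module TOM
  approaches the within-module level; dynamic tree cut is out of scope.
- The ORF surrogate ignores codon usage, Kozak context and similarity to
  known proteins; externally computed coding-potential scores should be
  preferred when available.
- Cross-dataset catalogue reconciliation beyond transitive span merging is
  not attempted; published catalogue overlaps produced by other tools may
  not be exactly reproducible from merge semantics alone.
- Differential-expression calling is upstream: the network consumes a DEG
  id list (a convenience |log2FC| screen is provided but is not a
  statistical test).
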