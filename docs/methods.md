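# Methods

This note documents the models, parameter choices, and numerical conventions
behind larvatlas, and what the synthetic-data experiments do and do not
demonstrate.

## Data model and I/O

UMI matrices follow the 10x on-disk convention (MatrixMarket, genes × cells,
with barcode and feature TSVs) and are transposed exactly once at the reader
boundary; everything in memory is cells × genes. Gene ids (not symbols) are
the join key across all tables. Mitochondrial genes are identified by a
configurable feature-name prefix (default `mt-`, case-insensitive) because
mitochondrial annotation schemes differ per genome. Reals are written to TSV
at 6 significant digits; strings and integers round-trip bit-exactly.

## Quality control

A cell is removed when its detected-gene count is strictly below 200, its
mitochondrial count fraction strictly above 0.20 (0.30 in the flatworm
preset), or its total UMI strictly beyond 5000 on the configured side. The
UMI bound defaults to an *upper* bound — the literal protocol reading — but
the side is exposed as `umi_bound_side` because an upper bound of 5000 sits
oddly against droplet libraries averaging tens of thousands of UMIs per
cell; rather than silently "correcting" the protocol, the knob is surfaced.
Genes left with zero counts after cell filtering are dropped and listed.
Filtering is idempotent.

## Normalization and variable genes

Expression is `ln(1 + s · c_gc / Σ_g c_gc)` with scale s = 10,000, which is
invariant to per-cell depth rescaling. Variable genes use the vst flavor:
per-gene raw-count mean and variance, a lowess trend of log10 variance on
log10 mean (span 0.3), per-gene standardization by the trend-expected
standard deviation with values clipped at √n_cells, and ranking by the
variance of the clipped values. The trend constants (span, clip ceiling) are
the community defaults for this method; ties break deterministically by gene
id, and constant genes (score 0) can never outrank a varying gene.

## Embedding and over-clustering

PCA (exact full SVD) runs on the selected genes after per-gene centering,
unit-scaling, and clipping at ±10. The per-axis sign ambiguity is fixed by
forcing each axis's largest-magnitude loading positive, making the embedding
fully deterministic. The shared-nearest-neighbor graph uses k = 20 neighbor
lists (self included), Jaccard edge weights, and pruning below 1/15; it is
partitioned with seeded Leiden modularity optimization at resolution 10 by
default. High resolution deliberately over-clusters; the merge stage is the
corrective. External labels can be supplied instead, bypassing clustering.

## Iterative cluster merging

Each pass recomputes cluster centroids (arithmetic means of log-normalized
expression), ranks all unordered cluster pairs by Pearson correlation
descending (ties lexicographic; constant centroids get r = 0 with a
warning), and walks the list testing pairs: per gene a two-sided Wilcoxon
rank-sum test with normal approximation, tie correction, and 0.5 continuity
correction; a gene is differentially expressed when its Bonferroni-adjusted
p (across genes, within the pair) is below 0.01 **and**
|log2((mean_a + ε)/(mean_b + ε))| ≥ 0.25 with ε = 1e−9. The first pair with
strictly fewer than 20 DE genes merges (the lexicographically smaller id
survives), the pass restarts, and the loop ends when a full pass makes no
merge — at most (initial clusters − 1) merges. Pairs where either side has
fewer than 3 cells are never merged: the rank-sum test is uninformative
there. Bonferroni at 0.01 and the 0.25 fold-change floor are deliberate
conservative choices — they bias toward merging, i.e. toward keeping only
clusters that are distinct beyond doubt. The rank-sum statistic is verified
against exhaustive pair-count/permutation enumeration for group sizes ≤ 6
and against an independent library implementation.

## Transcriptome age index and enrichment

Phylostratum ranks (1 = oldest) are the age values; the TAI of a cluster is
the rank mean weighted by the centroid's log-normalized expression,
restricted to genes with positive centroid expression and an age assignment
(genes without ages are excluded and counted, never imputed; a cluster with
no aged genes reports a missing TAI, not zero). A weighted mean of a
constant is returned as that constant exactly. Marker genes are one-vs-rest
two-sided Wilcoxon with Benjamini–Hochberg across genes within each cluster
(adjusted p < 0.05, log2 fold-change ≥ 0.25, in-cluster mean higher); these
defaults are this package's own, documented rather than claimed to replicate
any particular study's unstated marker test. Enrichment of cluster markers
per phylostratum is the upper-tail hypergeometric probability P(X ≥ k)
against the expressed, aged background; k = 0 gives p = 1 exactly and
clusters without markers are flagged. Raw p is reported (−log10 with a
1e−300 floor) because the heat-map convention for this analysis is raw
p-values; a BH-adjusted column across the grid is additionally emitted.

## Cross-species alignment

The module implements the alignment *score*, not a full alignment toolchain:
no expression-driven reweighting of the homology graph is performed. Shared
features are connected components of the ortholog graph restricted to genes
present in both matrices (records naming absent genes are skipped with a
count; single-species components are dropped and counted); a species'
feature value is the weight-normalized average of its member genes, a gene's
weight being the sum of its ortholog-edge weights in the component. After
per-species feature standardization the rows are stacked and embedded with
the same sign-fixed PCA (d = 30). Mutual nearest cross-species neighbors
(Euclidean, distance ties broken by cell id) define the score of a cluster
pair (c, d): the mean over cells of c of their mutual-partner count in d
divided by k, symmetrized with the opposite direction, hence in [0, 1].
k = 20 by default; the symmetric mean is used because "average per cell"
does not fix a direction, and both the full and the pruned (< 0.1 zeroed)
matrices are emitted so either reporting convention can be applied. Shared
markers of an aligned pair are exactly the ortholog records joining the two
marker sets; distinct-gene counts per species differ under many-to-many
homology by construction.

## Neuropeptide precursor scan

Secretion calls come from an external table when provided (a `d_score`
column is thresholded at 0.34, the sensitive cutoff convention for such
tables); otherwise a deliberately crude built-in heuristic stands in: a
protein ≥ 30 residues is called secreted when some 8-residue window in the
N-terminal region has mean Kyte–Doolittle hydropathy ≥ 1.6 and the first
five residues contain a basic residue or the initial methionine, with the
cleavage position at the best window's end + 3 (heuristic calls stay within
residue 45). The heuristic is a stand-in for a dedicated signal-peptide
predictor and is always overridden by an external table.

Downstream of the signal peptide, dibasic sites are consecutive K/R pairs
resolved left-to-right without residue re-use; monobasic sites are remaining
K/R residues with a *free* basic residue (not one consumed by a dibasic
site) exactly 2, 4, or 6 residues upstream — requiring the upstream context
to be free keeps basic residues inside mature peptides (an R in an
FMRFamide-type peptide adjacent to a dibasic site) from triggering spurious
cleavage. Peptides are the segments bounded by the signal/sites on the left
and a site on the right; the unbounded C-terminal tail is never a peptide,
so a site-free protein yields none. A C-terminal glycine immediately before
the downstream site marks amidation and is trimmed; flanking basic residues
are trimmed; length bounds are 3–40 with oversize segments counted. Every
residue of the post-signal sequence is assigned to exactly one recorded
segment (site, peptide, amide glycine, basic flank, discard, tail), so a
conservation audit can reconstitute the sequence exactly. Ranking keeps
secreted candidates with ≥ 2 peptides and orders by (peptide count,
amidated count, best gap-free pairwise peptide identity) descending; this
is an automatic stand-in for manual curation and is expected to interleave
with basic-residue-rich false positives on raw peptide count — the amidated
repeat structure is the discriminative signal.

## Synthetic data

All generators are pure functions of a `SimSpec` (seed included) and write
their ground truth next to the data. Counts are negative binomial
(gamma–Poisson, var = μ + αμ² with α = 0.5, the typical over-dispersion
regime for droplet UMI data) with per-cell depth uniform in 1000–3000,
gene baseline proportions log-normal(0, 1), and disjoint marker programs of
20 genes per type shifted up by 2 in log2 — defaults sized so a full
recovery run is seconds, not minutes. Marker genes' baseline expression is
floored at the pool median: a planted program whose genes are almost never
observed at the simulated depth is not a usable marker program, and without
the floor the planted types are not reliably distinct at the stated DE
threshold. Ten mitochondrial genes give most cells a 1–8% mitochondrial
fraction while 5% of cells draw 30–50% to exercise the QC filter.

Gene ages are uniform over 8 strata except the designated young cluster's
markers, which take the youngest stratum with probability 0.8 — emulating a
recently evolved cell type whose program is dominated by young genes.

The species-pair generator defines 400 ancestral features; each species
carries one gene per feature, or two paralogs for a feature independently
duplicated with probability 0.3 per species (all genes of a feature are
connected in the ortholog map, weight 1, making it partly many-to-many).
Three shared types up-shift the same feature blocks in both species; each
species additionally has one private type whose markers are unmapped
species-private genes *and* which up-shifts a species-specific block of
mapped features (width 3 × 20). The second part is essential: with unmapped
markers alone, both species' private types collapse to background in
ortholog space and spuriously become each other's mutual nearest neighbors;
the species-specific signature makes a private type geometrically private,
which is the property the planted truth asserts.

Precursor proteomes plant signal peptides (M + basic + 10 hydrophobic + 4
polar residues), five similar peptide repeats (8–12 residues from an
alphabet excluding K, R, and G so planted boundaries are unambiguous, one
substitution per copy) separated by KR sites with amidation glycines at 60%
of sites, and a polar tail, among 500 random decoys (half with
signal-peptide-like N termini).

What passing these simulations shows — and does not. The generators emulate
the statistical skeleton the methods assume: over-dispersed counts, disjoint
marker programs, age-skewed markers, partly many-to-many homology, clean
cleavage grammar. They contain no ambient RNA, doublets, batch effects,
continuous differentiation trajectories, correlated marker programs, or
homology errors, so parameter recovery here demonstrates correctness of the
implementation under its own model, not robustness of the methods on real
atlases.

## Pipeline

`run_all` chains QC → normalize → variable genes → PCA → initial clusters
(or external labels) → merge → markers → TAI + enrichment, with optional
cross-species alignment (when a second species and ortholog map are
configured) and precursor scan (when a proteome is configured). The YAML
config is schema-checked (unknown keys rejected), inputs of enabled stages
are verified before any compute, a resolved-config copy is written next to
the outputs, stage failures halt with the stage named (CLI exit codes:
2 config, 3 stage), and identical config + inputs reproduce byte-identical
tables — everything stochastic takes the single config seed.

## Problem sizes

The test suite and acceptance script run the recovery experiments at the
generator defaults (300 cells × 2000 genes × 5 types; 60 cells/type for the
merge recovery at k ∈ {2, 4, 6}; 300 cells per species × 400 ortholog
features; 20 precursors among 500 decoys), with 100 seeded replicates per
recovery claim in the test suite and 25–30 in the acceptance script. Exact
oracles (permutation enumeration for rank-sum groups ≤ 6, hypergeometric
tail sums for N ≤ 30) run exhaustively at those sizes.

## Known limitations

Single-library path only (no multi-library integration or batch
correction); the alignment module scores a fixed ortholog map rather than
refining it; the marker test and the monobasic cleavage grammar are
documented conventions, not reconstructions of any specific prior tool's
internals; the signal-peptide heuristic is intentionally simple and should
be replaced by external calls whenever available; gene ages are consumed,
never computed.
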