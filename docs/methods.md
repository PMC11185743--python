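# Methods

This note documents the models, parameter choices, and numerical
conventions behind `dopamap`, and what the synthetic-data tests do and do
not demonstrate about real data.

## The synthetic study

The generator emulates a single-nucleus survey of midbrain dopamine
neurons with a planted three-level taxonomy. Its defaults define the
study conditions used throughout the test suite and the acceptance
script.

**Taxonomy and markers.** Three families, each a balanced binary subtree
over its leaves (default 2 leaves per family → 6 subtypes, 5 internal
nodes). Every internal node carries `markers_per_node = 10` unique marker
genes per side, multiplied `effect_size = 4`-fold in all cells descending
through that side. Ten markers per branch reflects how real subtype
branch points behave: they are separated by dozens of co-regulated genes,
several near-binary, rather than by one or two. With sparser markers
(say 3 per node) the planted sex and genotype structure — which real
datasets carry without re-clustering by it — would dominate the subtype
signal at this gene-universe size, which contradicts the phenomenon being
emulated.

**Baseline expression.** Per-gene relative abundance is lognormal
(σ = 1.2, normalized to a simplex). Branch-marker genes are re-drawn from
a moderate band (5×10⁻⁵–9×10⁻⁵ relative abundance ≈ 0.25–0.45 expected
counts at the default 5000-UMI depth). In that band a 4-fold shift moves
detection from ~20–30% to ~60–80% of cells — the near-binary detection
difference that marker thresholds built around `min.diff.pct` and
`|log2FC| ≥ 1` (with +1 pseudocounts) are designed to find. Markers drawn
at arbitrary baselines either saturate detection (high baseline, failing
the detection-difference filter) or fall below the pseudocount-dominated
fold-change floor (low baseline); neither is how subtype markers present
in real data. Genotype-effect genes are placed in a robustly detected
band (4×10⁻⁴–2×10⁻³) so a 2-fold effect is measurable; glial markers are
silenced (×10⁻⁴) in the dopaminergic baseline, as real glial transcripts
are in neurons.

**Counts.** Negative binomial with shared dispersion r (default 10;
variance μ + μ²/r) and per-cell lognormal depth factors (σ = 0.35 around
`depth_mean = 5000`). The tests verify the NB moments directly (Poisson
limit as r → ∞ and the closed-form variance at r = 2). Real data are
noisier in ways this model omits: gene–gene correlation beyond the
taxonomy, batch and ambient-RNA structure, and cell-cycle or activity
states. A passing recovery test therefore shows the pipeline is correct
and well-calibrated under a clean count model — not that real datasets of
this size will cluster this cleanly.

**Sex, doublets, genotype, space.** Two male-specific and two
female-specific genes are expressed at ~20 counts in the matching sex and
zero in the other; 5% of cells drop both sets ("indeterminate", the third
peak of the sex-ratio histogram). Doublets (3%) are 50/50 expression
mixtures of one dopaminergic leaf and a glial profile, carrying their own
truth label. The genotype multiplies 8 global and 4 family-scoped genes
×2 in mutant cells, with leaf proportions untouched. The spatial dataset
restricts to the ~120-gene panel (all branch markers plus filler), forces
2 failed-probe genes to zero, lowers depth to 250 transcripts, draws
lognormal cell volumes (median 1500 µm³), and places each leaf mostly
(90%) in one of four rectangular regions in µm coordinates, 6%
"elsewhere" in the gaps. Rectangles stand in for real anatomical
polygons; the point-in-polygon machinery is exercised against a
ray-casting oracle independently.

## Taxonomy pipeline

Normalization is counts → per-cell scaling to `target_sum = 10⁴` →
`log1p` → per-gene z-score clipped at ±10 (constant genes get zeros;
zero-depth cells are excluded with a warning). PCA (default 32
components, deterministic full SVD) fixes each component's sign so its
largest-magnitude loading is positive, making scores reproducible across
BLAS builds.

Clustering builds the exact k-nearest-neighbor graph (k = 40, Euclidean
in PC space, neighborhoods include the cell itself), converts to SNN
Jaccard weights pruned below 1/15, and optimizes resolution-parametrized
modularity with the seeded Leiden implementation (resolution 0.8).
Singleton communities are merged into the nearest cluster by centroid
distance; labels are relabeled by decreasing size. The dendrogram is
average-linkage agglomeration of cluster centroids in PC space.

Node markers use the two-sided Wilcoxon rank-sum test (normal
approximation with tie correction; a gene constant across both groups
gets p = 1), Seurat-style log2 fold changes with +1 pseudocounts on the
expm1 scale, and BH adjustment over tested genes. Rows sort by |log2FC|
descending, then p, then gene id — fully deterministic where the original
workflow involved manual curation of branch markers.

**Stepwise codes** take the top `markers_per_node = 3` upregulated genes
of each side along the root-to-leaf path. Three genes per branch, rather
than one, is deliberate: a single 4-fold-enriched gene detected in ~30%
of off-target cells is a leaky literal gate, and conjunction across three
markers per branch restores ≥0.8 median precision while keeping the
recipes short enough to read as intersectional labels. Codes are unique
by construction (distinct paths); the renderer emits `gene+ & gene+ & …`.

**Stability** resamples `downsample_frac = 0.8` of cells without
replacement, re-runs normalize/reduce/cluster with the original
parameters, and scores each original cluster by a pair-Jaccard
co-clustering score: with O the retained within-cluster pairs and N the
retained pairs sharing a replicate cluster with at least one endpoint in
the original cluster, score = |O∩N| / |O∪N|. The score is 1 exactly when
the cluster reappears unchanged and is depressed both when its cells
scatter and when it absorbs outsiders; a pure "fraction of within-pairs
preserved" score is blind to merging (a cluster whose split was arbitrary
would look perfectly stable once its halves re-merge), which defeats the
purpose of the measure. Box-plot summaries use 1.5×IQR whiskers with
outliers listed.

## Spatial mapping

Shared features keep panel genes detected in ≥1% of cells in both
datasets whose query/reference mean-count ratio lies within 4-fold
(`max_ratio = 4` is the package's operationalization of "similar average
counts"; failed probes are excluded automatically by the detection
floor). Both datasets are z-scored with their own statistics on the
shared genes, and the query is projected into the reference PCA basis
using the reference centering vector (clipping makes the z-scored matrix
mean slightly nonzero, so skipping the centering would offset the two
datasets). Anchors are mutual nearest neighbors at `k_anchor = 5`, scored
by the overlap of their `k_score = 30` joint-space neighborhoods (self
included, so identical profiles score 1).

Transfer weights each query cell's `k_weight = 50` nearest anchors with a
Gaussian kernel (bandwidth = distance to the k-th anchor) times the
anchor score, normalized to sum 1. An anchor coincident with the query
cell on both of its sides is an exact profile match and takes the entire
weight — the tie-break that makes mapping a dataset onto itself reproduce
it exactly rather than smooth it (the round-trip fidelity check).
Predicted-label scores sum anchor weights per reference label; the
prediction is the argmax, gated at 0.5. Imputation is the anchor-weighted
average of reference normalized expression (hence convex per gene).
Fidelity is the per-gene Pearson r over cells non-zero in both matrices,
NA below 10 such cells — failed probes surface as NA/low fidelity.

Region assignment is first-polygon-wins in priority order, boundary
inclusive, "elsewhere" otherwise; composition tables are emitted
row-normalized (within region) and column-normalized (within group).

## Genotype contrasts

`condition_de` runs the marker machinery with `min_pct = 0.10` (detection
in either condition), no fold-change or detection-difference floor, and
reports FDR-significant counts plus the |log2FC| > 0.5 subsets. Group A
is the first condition in sorted order, so with "control"/"mutant" labels
a mutant upregulation appears as negative log2FC. Per-cell DE treats
cells as independent; outputs carry a pseudoreplication warning, and
pseudobulk is intentionally out of scope at two libraries per condition.
Proportion shifts use condition-label permutation (|Δproportion| statistic,
+1-smoothed p, BH) — a test added for rigor where the original comparison
was descriptive. Cluster similarity is neighbor voting: Spearman
correlations over variable genes (per dataset, genes binned into deciles
by mean; above-bin-median variance-to-mean dispersion, top decile
excluded; intersected across datasets), votes = mean correlation to the
source cluster, AUROC of votes over the target dataset's cells.
Similarity runs on normalized counts; any imputed/smoothed matrix can be
passed instead. Low-rank dropout correction is intentionally not
reimplemented.

## Enrichment

The preranked statistic walks genes in decreasing score order; hits
increment by |score| (weight exponent 1, normalized by the hit total),
misses decrement by 1/(N−k); ES is the extremum of the running sum,
evaluated only at hit boundaries where extrema can occur. The null draws
`n_perm` random same-size gene sets from the ranked universe; p is
two-sided on |ES| with +1 smoothing (the null-uniformity test pins this
calibration), and NES divides ES by the mean |null ES| of matching sign.
Whether the original analysis used one- or two-tailed p per sign is not
restated anywhere; two-sided with sign-matched NES is this package's
choice. Over-representation is the upper-tail hypergeometric with a
caller-supplied background — the detection-filtered universe of the
contrast that produced the hits — so that results are not trivially
enriched for cell-type-specific pathways. Synaptic fractions report
compartment and function counts with the finer labels (presynaptic,
postsynaptic, active zone) implying the synaptic parent.

## Risk scoring

Weights are z/(σ_g + ε) with ε = 0.05 on normalized expression (the
inverse-variance option; the exact reference formula is not restated in
the literature this emulates, so ε and the Σ|w| normalization are
documented choices validated by the null-calibration tests). Control
sets replace every risk gene by a uniform draw from its 20×20
(mean, variance) equal-frequency expression bin, inheriting the z;
normalized score = (raw − mean_ctrl)/sd_ctrl per cell, plus a +1-smoothed
Monte-Carlo p. Group inference bootstraps cells within groups (10,000
resamples, percentile 95% CI), significant iff the CI excludes 0. The
scoring universe defaults to the full normalized matrix; restricting to
highly variable genes is left to the caller, since the upstream
convention is ambiguous on this point.

One property of the group-level bootstrap deserves emphasis. The
normalized score of every cell in a dataset is computed against the
*same* risk set and the *same* control draws, so the control-matching
residual and the Monte-Carlo noise are shared across cells: each null
dataset carries a common score offset that resampling cells cannot
average away. Cell-level inference is unaffected — the per-cell
Monte-Carlo p compares the cell's raw score against its own control
distribution and is uniform under the null (verified across replicate
datasets). Group-level inference is affected: because cells are treated
as independent, the bootstrap CI of a group mean is too narrow relative
to the shared offset, and the false-significance rate of the CI-excludes-0
rule under a null risk set runs two to three times the nominal level in
the calibration study (2000-gene universe, 20×20 bins, 200 control sets,
groups of ~100 cells). The effect is intrinsic to combining shared
control normalization with a cell-resampling bootstrap — not a matter of
bin grid, universe size, control count, or risk-set size, all of which
were varied without closing the gap; at desk scale a few-hundred-gene
universe even masks it, since the bin grid then collapses to single-gene
pools whose "controls" are the risk genes themselves and every score is
driven to zero. The corresponding calibration check is left failing by
design, and comparative statements (which group scores highest) remain
meaningful because the offset is shared by all groups of a dataset.

## Orchestration and determinism

A single global seed fans out to stages via SHA-256 of
`(seed, stage-name)` (kept below 2³¹), so adding a stage never shifts
another stage's stream. All tables are written with explicit headers,
UTF-8, and 17-significant-digit floats; re-running a config reproduces
byte-identical outputs (hashed in the run manifest). Problem sizes in the
default config (600 genes, 3000 cells, 1500 spatial cells, 200-set GSEA
nulls, 20–50 replicate null datasets for risk calibration) were chosen so
the full synthetic study runs in minutes on one core while keeping every
planted effect measurable with comfortable margins.

## Known limitations

- The generator has no transcriptome-wide co-expression, batch effects,
  or ambient RNA; recovery margins on real data will be narrower.
- Normalization is the documented log1p/z-score path; results on real
  data will differ from variance-stabilizing (SCTransform-style) or
  CCA-integrated pipelines, which are intentionally not reimplemented.
- The anchor machinery projects the query onto the reference PCA (no CCA);
  with strong technology-specific distortions beyond per-gene scaling the
  anchors will degrade before the reference implementation's would.
- The stability score is this package's formalization; published
  stability numbers computed with other scripts are not directly
  comparable.
- Spatial regions are 2-D per section; no atlas registration.
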