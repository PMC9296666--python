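# Methods

## Model

The analysis treats each tumour cluster's pseudobulk profile *m* (average
log1p-normalized expression over the cluster's cells) as an approximate
mixture of reference cell-type profiles: *m* ≈ **S** *w* with *w* ≥ 0 and
Σwᵢ = 1, where **S** is the signature matrix of per-type average
normalized expression restricted to an informative gene universe. The
fractions *w* are "relative": they describe similarity-weighted
composition on the shared gene set, not absolute cell counts. A reference
type is called a *match* for a mixture when its estimated fraction reaches
the abundance cutoff (0.2 by default, inclusive boundary).

## Preprocessing

Cell QC applies three rules in a fixed order, each a pure function of the
matrix and thresholds:

1. cells with fewer than `min_genes` (default 1000) detected genes are
   removed (strict `<`);
2. cells whose mitochondrial count fraction exceeds the per-sample
   threshold `mito_max` (strict `>`; default 0.10, configurable per sample
   — typical practice sets it between 0.05 and 0.15 per sample) are
   removed; the fraction is computed on raw counts;
3. cells whose detected-gene count exceeds the per-sample
   `median + doublet_k · SD` (default k = 4, sample SD, both statistics
   computed *after* rules 1–2) are removed as suspected doublets. The rule
   is applied exactly once — iterating it could cascade and would make the
   removal set depend on the iteration count.

Sex-linked genes (Xist, Tsix, Eif2s3y, Ddx3y, Uty, Kdm5d; case-insensitive
match) are dropped after cell QC and before normalization. Normalization
is global scaling: `log(1 + count / cell_total × scale_factor)` with
`scale_factor` 10,000 (the conventional value for this scheme). The G0/G1
gate relabels upstream G1 calls as G0 unless a proliferation gate gene
(Top2a or Mki67 by default) has normalized expression strictly above 1;
upstream S/G2M calls pass through, and the upstream phase classifier is an
input, not part of this package.

## Marker detection and signature assembly

One-vs-rest differential expression per cluster uses the two-sided
Wilcoxon rank-sum test. Genes are screened first by expressing-cell
fraction in the cluster (`pct_in ≥ 0.5`) and by average log fold change
(`avg_lfc ≥ 0.5`), then tested; this screening changes nothing about which
rows are retained and avoids testing genes that cannot pass. The LFC
convention is natural log of `(mean(expm1(x)) + 1)` ratios between cluster
and rest, computed on log1p-normalized values. P-values are BH-adjusted
within each cluster over the tested candidates and rows with adjusted
p ≥ 0.05 are dropped (configurable; `pct_out` is reported for diagnostics
but not filtered on).

The rank-sum p-value is exact for small pooled samples (total n ≤ 30): the
permutation distribution of the rank sum is enumerated over all group
assignments, which handles ties correctly; larger samples use the
tie-corrected, continuity-corrected normal approximation (the same hybrid
R's `wilcox.test` uses). The test suite checks the small-sample path
against an independently written enumeration oracle.

The signature gene universe is the union over clusters of retained DE
genes, minus the union of the four exclusion families (cell cycle /
proliferation, ribosome biogenesis, mitochondrial, apoptosis — supplied as
files or generated synthetically), translated through the ortholog map.
The default ortholog policy `one_to_one_only` drops every source gene that
shares a target symbol with another source, so the retained map is
injective; with source-namespace exclusion sets and an injective map,
excluding before or after translation gives the same matrix. Signature
values are arithmetic means of log1p-normalized expression per cluster —
the average is taken on the log scale, matching the "normalized average
expression" convention of the upstream toolchain. Clusters with fewer than
`min_cells` (default 20, `≥` kept) cells are removed before assembly.

Marker ranking for presentation uses the minimum pairwise LFC: for cluster
c and gene g, the minimum over all other clusters c′ of lfc(c vs c′); a
gene with a large minimum separates the cluster from every other cluster
rather than just from the pooled rest.

`shared_signature_genes` scores the genes a tumour profile shares with its
matched reference type as the difference in average normalized expression
(tumour − reference). Because the underlying description is a single
sentence, the concrete ranking here is an interpretation: genes with both
values above an expression floor (default 0.5) are ranked by ascending
absolute difference, ties broken toward higher shared expression, so genes
highly expressed in both with small difference rank first.

## Deconvolution engines

All engines share the post-processing contract: raw coefficients are
clipped at zero and renormalized to sum to 1; an all-non-positive raw
vector yields an all-zero column flagged degenerate rather than an error.
Fit quality is reported per mixture as the RMSE and Pearson r of
**S** *w* against *m*.

* **nnls** — `min ‖S w − m‖²` s.t. `w ≥ 0` (active-set NNLS). Exact on
  noise-free convex combinations; serves as the oracle for the other two.
* **nusvr** — linear ν-support-vector regression of the mixture on the
  signature columns. The signature is standardized with its *global* mean
  and SD (a single scalar pair for the whole matrix) and the mixture with
  its own; standardizing each column separately would rescale each cell
  type by its own SD and bias the renormalized fractions, which is
  measurable even at zero noise. Each ν in {0.25, 0.5, 0.75} is fitted
  (C = 1); the clipped, sum-normalized coefficients are used to
  reconstruct the standardized mixture and the ν with the lowest
  reconstruction RMSE wins, ties toward smaller ν for determinism. A
  solver failure at one ν skips that ν; failure at all ν is an error.
* **dwls** — iteratively reweighted NNLS starting from the NNLS solution,
  with gene weights `1 / max((S w)², damping)` (damping default 1e-4 on
  the squared normalized-expression scale, guarding genes reconstructed
  near zero), iterated until the relative change in `w` falls below `tol`
  (1e-6) or `max_iter` (100); non-convergence returns the last iterate
  with a flag.

All three engines are deterministic; no randomness enters after the
synthetic inputs are drawn.

## Match calling and reporting

Matches use `fraction ≥ cutoff` (inclusive — the boundary semantics are a
package decision since only the cutoff value itself is conventional).
Raising the cutoff can only shrink match sets. The overlap summary counts
mixtures per *exact* combination of matched types, so counts partition the
matched mixtures. Hierarchical clustering of mixtures on their fraction
vectors defaults to euclidean distance with average linkage (the defaults
of the common heatmap tooling; correlation distance and complete/Ward
linkage are available, Ward requiring euclidean), and the dendrogram is
serialized as Newick with branch lengths from merge heights. Recovery
metrics (synthetic runs only) report per-type MAE, overall Pearson r over
all (type, mixture) pairs, and the sensitivity/specificity of thresholded
match calls treating `truth ≥ cutoff` as positive.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
any particular dataset:

* **Atlas** — each of `n_cell_types` types owns a disjoint block of
  `markers_per_type` marker genes whose negative-binomial mean is
  `marker_fold_change` × baseline in cells of that type. Counts are NB
  with mean/size parameterization (Var = μ + μ²/size). Defaults: baseline
  mean 0.5 and dispersion (size) 2.0, giving ~35 % expressing cells for
  baseline genes — 10x-like sparsity; log-normal per-cell library factors
  with σ = 0.2, a typical depth spread. Timepoint labels per type emulate
  a multi-timepoint atlas with temporally restricted types.
* **Ortholog map** — a chosen fraction of genes (default 0.9 in the
  pipeline) receives a unique target symbol; the map is injective by
  construction, so many-to-many resolution is exercised only through the
  mapping policy.
* **Mixtures** — known convex combinations of signature columns plus
  i.i.d. Gaussian noise with per-gene SD `noise_sd ×` (the gene's mean
  signature expression), truncated at zero. The additive
  Gaussian-on-signature-scale model is a calibration choice that makes
  engine comparisons interpretable, not a claim about real pseudobulk
  noise; the pipeline default `noise_sd = 0.05` represents a moderately
  noisy pseudobulk. Ground-truth compositions activate 3 types per mixture
  with Dirichlet(1) weights (optionally one dominant type with fraction
  uniform in [0.6, 0.9] and designated always-zero types).

What passing on synthetic data does **not** show: robustness to batch
effects, ambient RNA, doublet transcriptomes, platform differences between
reference and tumour data, imperfect ortholog annotation beyond random
dropout, or cell types absent from the reference — real analyses must
assess those separately.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale study conditions chosen once:
engine recovery on a 20-type, 2000-gene atlas (40 markers/type, fold
change 8, 50 cells/type) with 40 mixtures; signature fidelity on an 8-type
atlas with 50 markers/type; the embryonic-vs-adult matching property on a
10-type atlas over 40 seeded replicates at `noise_sd` 0.05; and a
signature-size check on a 20-type, 6000-gene atlas with 150 markers/type,
which lands in the low thousands of genes after ortholog mapping, the
range typical of real cross-species signatures.

Degenerate inputs are handled explicitly: zero-total cells fail
normalization with the cell named; an all-zero mixture yields a flagged
all-zero fraction column; a constant reconstruction reports Pearson r as
NA; empty gene universes name the filter that emptied them. Fraction
columns are validated to sum to 1 within 1e-9 (or exactly 0 when
degenerate) and ground-truth columns to 1 within 1e-12.

## Known limitations

* The atlas generator plants marker modules with a single shared fold
  change and no correlation structure between genes; graded or overlapping
  marker programs (e.g. lineage continua) are not simulated.
* The ν-SVR engine is the core fraction estimator of the published
  CIBERSORT family; its service-hosted batch-correction variant is out of
  scope.
* Upstream clustering, embedding, velocity and lineage-tree inference are
  deliberately not part of the package; cluster labels are inputs.
* `shared_signature_genes` implements a one-sentence description and its
  floor/ranking details are an interpretation (documented above).
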