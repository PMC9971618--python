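# pnmfmkl

Multi-omics data fusion and gene-signature detection: empirical-Bayes
feature screening, penalized non-negative matrix **tri-factorization** for
cross-platform fusion, soft-margin **multiple kernel learning** (MKL) for
class-label evaluation, and **topological-overlap** co-expression modules
with PAM-validated signature election.

## The problem

Tumor cohorts are profiled on several platforms at once — gene expression,
DNA methylation, exon expression, pathway activity, copy number — over a
shared set of patients that fall into a small number of clinical classes
(e.g. favorable / intermediate / poor risk). The goal is a single compact
*gene signature*: a group of co-expressed genes, assembled from evidence in
**all** layers, that discriminates the clinically relevant split of the
classes. `pnmfmkl` is for computational biologists who want that whole chain
as a reproducible, testable pipeline.

## The method

1. **Screening** (`diffexp`). Each layer is z-scored per feature and tested
   with a moderated statistic: the feature variance is replaced by the
   empirical-Bayes posterior blend
   `s̃² = (d₀s₀² + d·s²)/(d₀ + d)`, with `(d₀, s₀²)` estimated by moment
   matching on `log s²` across the layer. Two classes give a moderated t;
   more give a moderated F on `(m−1, d₀+d)` degrees of freedom. Per gene the
   minimum-p probe survives (p < 0.05); the per-layer gene sets are unioned
   into *UF*.
2. **Fusion** (`fusion`). Layers, genes and samples become object types of a
   relational block system; every relation `R_ij` is factorized as
   `R_ij ≈ G_i S_ij G_jᵀ` with shared non-negative per-type factors `G`,
   minimizing `Σ‖R_ij − G_i S_ij G_jᵀ‖² + Σ_p tr(GᵀτᵖG)` by alternating
   exact least squares on `S` and HALS on `G` (objective non-increasing).
3. **Kernels + MKL** (`kernels`, `mkl`). Reconstructed blocks give
   sample×sample kernels `K = R̂R̂ᵀ`, cosine-normalized, box-smoothed and
   PSD-projected. A hinge-loss soft-margin MKL learns convex kernel weights
   μ, a dual vector α, a target margin θ and per-kernel slacks
   `ζ_p = max(0, θ − D_SVM(K_p, α))`, minimizing `−θ + π·Σζ_p` with
   `π ≥ 1/P`.
4. **Label search** (`labelsearch`). All one-vs-one and one-vs-rest splits of
   the classes (six for three classes) are scored by stratified-CV pooled
   Mann-Whitney AUC of the MKL classifier; the argmax split goes forward.
5. **Modules + signature** (`netmodules`, `signature`). On the winning
   split's expression sub-data: soft-threshold power β (scale-free fit),
   adjacency `|PCC|^β`, topological overlap
   `TOM(i,j) = [Σ_v X_iv X_jv + X_ij] / [min(k_i, k_j) − X_ij + 1]`,
   average-linkage clustering of `1 − TOM`, dendrogram cut into modules.
   The module with the highest mean within-module Pearson correlation is the
   signature; it is validated with a nearest-shrunken-centroids (PAM)
   classifier under 10×10-fold cross-validation.

A seeded synthetic-cohort generator (`simulate`) with planted
equicorrelated modules and graded class shifts provides ground truth for
every stage.

## Worked example

```bash
pnmfmkl simulate --seed 3 --out simdemo/        # 3 classes × 40 samples, 2 layers
pnmfmkl run --data simdemo/ --out report.json --seed 3
```

prints

```
best combination: class1 vs class3 (AUC 0.7900); signature: 61 genes, mean AUC 0.9186
```

meaning: among the six binary class splits the extremes pair `class1 vs
class3` had the highest cross-validated MKL AUC (0.79); the elected
signature module holds 61 genes (mean within-module PCC 0.77, reported in
`report.json` under `signature.average_pcc`), and PAM separates the two
classes on those genes with mean AUC 0.92 over ten repeated 10-fold CVs.
`report.json` also carries the full combination table (sensitivity,
specificity, precision, NPV, accuracy, AUC per split), the module list with
mean correlations, and the cluster-validity indices (Dunn index, silhouette
width, density, centralization, heterogeneity, scaled connectivity,
clustering coefficient, maximum adjacency ratio).

The same stages are available as library calls (`pnmfmkl.run_pipeline`) and
as sklearn-style estimators (`TriFactorizer`, `SoftMarginMKL`,
`NearestShrunkenCentroids` with `fit`/`predict`/`get_params`).

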