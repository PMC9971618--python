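# Methods

This note documents the models, estimators and numerical choices behind
`pnmfmkl`, and what the synthetic-data experiments do and do not establish.

## Moderated statistics (`diffexp`)

Each layer is standardized per feature with the **population** standard
deviation (no Bessel correction; configurable via `ddof`). For a feature
with per-group means and residual variance `s²` on `d = n − m` degrees of
freedom, the posterior variance is the convex blend
`s̃² = (d₀s₀² + d s²)/(d₀ + d)`. The prior `(d₀, s₀²)` is estimated by
moment matching on `e = log s² − ψ(d/2) + log(d/2)`: under a scaled-F
sampling model, `Var(e)` exceeds the sampling term `ψ′(d/2)` by `ψ′(d₀/2)`,
which is inverted by Newton iteration; `d₀` is capped at 10⁶ (effectively
full shrinkage) and the cap is also used when the excess variance is
non-positive. Setting `d₀ = 0` recovers the classical pooled statistics
exactly — the suite verifies this against a longhand pooled-t oracle.

With `m > 2` classes the per-group means feed a one-way moderated F,
`F = [Σ_g n_g(x̄_g − x̄)²/(m−1)] / s̃²`, with p-values from
`F(m−1, d₀+d)`; for two classes this equals the squared moderated t, so the
pairwise and one-way routes agree. All pairwise moderated contrasts are also
retained. No multiple-testing adjustment is applied by default (raw
p < 0.05 keeps a feature); Benjamini–Hochberg is available via
`select_significant(..., adjust="bh")`. Probe-to-gene collapse keeps the
minimum-p probe, breaking exact ties on the lexicographically smallest
probe id for determinism.

## Tri-factorization (`fusion`)

Object types are `gene`, `sample`, and one feature space per layer; each
layer contributes a (features × samples) data block and a binary
gene-membership block. A layer whose features *are* gene symbols may
collapse into the gene type (one such layer at most, since a type pair can
hold only one relation). Blocks are shifted by their minimum to make them
non-negative (shift recorded, invertible); missing entries are masked out
of the objective and stored as zeros.

The objective `Σ‖M∘(R_ij − G_i S_ij G_jᵀ)‖² + Σ_p tr(G_pᵀ τ_p G_p)` with
`G_p ≥ 0` is minimized by block coordinate descent:

* `S_ij` — exact least squares `(G_iᵀG_i)⁺G_iᵀ R_ij G_j(G_jᵀG_j)⁺`
  (a few Lipschitz-stepped gradient iterations when the block is masked);
* `G_p` — HALS: each column is an exactly-solved non-negative least-squares
  coordinate step over all blocks touching the type, with incremental
  residual updates. A diagonal `τ_p` enters the column denominators
  exactly; an off-diagonal part is linearized.

Every sub-update is accepted only if the global objective does not
increase, so the recorded trace is non-increasing by construction, and an
internal guard raises if it ever rises beyond 1e−9 relative (update-rule
bug detector). Multiplicative gradient-split updates were evaluated first
and stalled at poor stationary points on planted problems; HALS is the
package's solver choice. Alternating descent is still init-sensitive, so
`n_init` restarts (seeded `seed + i`) are supported and the best final
objective is kept. Defaults: rank `min(⌈n_p/10⌉, 50)` per type, `τ = 0`,
tol 1e−6 relative, `max_iter` 500, half-normal initialization scaled by
`sqrt(mean|R|/r)`.

## Kernels and soft-margin MKL (`kernels`, `mkl`)

Each reconstructed (feature × sample) block, transposed so samples are
rows, gives `K = R̂R̂ᵀ` (PSD by construction). Kernels are then
cosine-normalized (`K_ab / √(K_aa K_bb)`), smoothed with a uniform
`window × window` moving average with edge replication (window 3 by
default, 1 disables; normalization precedes smoothing), symmetrized, and
projected to the PSD cone by clipping negative eigenvalues — smoothing is
the only step that can break PSD. Smoothing couples samples that are
*adjacent in matrix order*; the sample order is the deterministic
lexicographic order from `intersect_samples` and must not encode the
phenotype (the synthetic generator therefore scatters classes over sample
positions, as accession order does in real cohorts).

The MKL program minimizes `−θ + π Σ_p ζ_p` subject to
`D_SVM(K_p, α) ≥ θ − ζ_p`, `ζ_p ≥ 0`, where
`D_SVM(K, α) = Σα_n − ½ΣΣ α_nα_m y_ny_m K_nm` and `π ≥ 1/P` is required
for feasibility. At `π = 1` this is the maximin program
`max_α min_p D_SVM(K_p, α) = min_μ max_α D_SVM(K_μ, α)` — the classical
margin-maximizing MKL objective over convex kernel weights. The solver
alternates: (a) an SVM dual solve on `K_μ = Σμ_p K_p` (libsvm via
scikit-learn, box constraint `C`, default 1 — the dual as written has no
per-sample slack, so the box is a solver-level decision); (b) closed-form
`θ, ζ`: with `k = ⌈1/π⌉`, `θ` is the k-th smallest `D_SVM` and
`ζ_p = max(0, θ − D_p)`; (c) an exponentiated-gradient step on μ along the
per-kernel margin norms `q_p = αᵀYK_pYα` (the descent direction of the
combined dual value in μ), with backtracking on the step size so the
objective never increases. Kernels with equal `q` keep equal weights;
identical kernels end at uniform weight. The reported θ is
`min_p (D_p + ζ_p)`. The decision score is
`Σ_n α_n y_n K_μ(n, s) + b`, `b` from the KKT condition averaged over free
support vectors.

## Label-combination search (`labelsearch`)

For `m` classes, the candidates are all one-vs-one pairs and one-vs-rest
splits, deduplicated under side swap (six for `m = 3`, `C(m,2) + m`
otherwise, minus the `m = 2` duplicate). Each candidate restricts the
kernels to its samples and runs stratified k-fold CV (default 10, reduced
with a warning if a class is smaller) of the MKL classifier; out-of-fold
decision scores are pooled into one Mann-Whitney AUC (rank formula, ties
half-weighted — verified against the concordant-pair count) and
threshold-0 confusion metrics. The winner is the max-AUC split, ties broken
by accuracy then lexicographic name. Because screening and fusion see all
samples, these CV numbers are transductive and
are used *comparatively* across splits, not as unbiased generalization
estimates; the splits share any selection optimism.

## Network modules (`netmodules`)

The adjacency on the winning split's expression sub-data is
`|PCC|^β` (unsigned network, the historical default; a Boolean
thresholded mode is available since the overlap formula is stated for
Boolean entries but is well defined on [0, 1]). β is the smallest candidate
(default 1…10) whose connectivity distribution fits a power law with
R² ≥ 0.8 on a 10-bin log-log regression, falling back to the argmax when no
candidate reaches the target — scale-free structure is an assumption about
real co-expression networks that planted-block data do not satisfy, so the
fallback is the common path in the tests.

TOM is evaluated exactly as
`[Σ_{v≠i,j} X_iv X_jv + X_ij]/[min(k_i,k_j) − X_ij + 1]` (diagonal 1), and
`dissTOM = 1 − TOM` feeds average-linkage (UPGMA) clustering. Modules are
the branches obtained by cutting every merge above `cut_height = 0.99` on
the dissTOM scale — the "largest merge heights" cut: genuine modules join
the rest of the tree at near-maximal dissimilarity while a homogeneous
dendrogram (root below the cut) stays a single module. Branches smaller
than `min_module_size` (default 20) fall into the grey pool, excluded from
signature election. A recursive height-gap rule was tried first and
rejected: under average linkage, background genes chain into module
branches and erase the gap at the nodes the recursion visits.

Validity indices use the standard weighted-network concepts: density
(mean off-diagonal adjacency), centralization, heterogeneity (coefficient
of variation of connectivity), mean scaled connectivity `k/k_max`, weighted
clustering coefficient, maximum adjacency ratio `Σa²/Σa`, Dunn index
(min inter-module dissimilarity over max intra-module diameter) and
silhouette width on dissTOM. With a single module, Dunn and silhouette are
reported as 0 by convention.

## Signature election and PAM (`signature`)

Each non-grey module's score is the mean Pearson correlation over all
unordered within-module gene pairs on the selected samples; the argmax is
the signature (ties: larger module, then lexicographic id). PAM (nearest
shrunken centroids) standardizes centroid offsets by `m_k(s_j + s₀)` with
`s₀` the median pooled within-class sd, soft-thresholds them by Δ, and
classifies by shrunken-centroid discriminant with class priors. Δ is chosen
by inner 5-fold CV on a 30-point grid from 0 to the largest standardized
offset, ties preferring stronger shrinkage. At Δ = 0 the rule is exactly
diagonal-covariance nearest-centroid classification (oracle-checked), and
increasing Δ can only remove genes (monotone elimination). Evaluation:
10 repeats of stratified 10-fold CV (seeds `seed + r`), per repeat pooling
out-of-fold predictions into one confusion matrix and posterior scores into
one AUC; the report gives mean ± sd over repeats. Whether to pool or
average per-fold AUCs is a genuine choice; pooling per repeat is used for
stability at small n.

## Synthetic cohort (`simulate`)

The generator emulates a three-class tumor cohort: a latent gene × sample
matrix with block-equicorrelated modules
(`gene = √ρ·factor + √(1−ρ)·noise`, so within-module correlation is ρ in
expectation), a graded mean shift on the signature module's genes
(fractions 0…1 of δ across the ordered classes — an ordered-severity
design, so the extreme pair carries the largest contrast), and per-layer
observations `slope·latent + noise` with per-feature slopes ~U(0.5, 1.5),
multi-probe genes, and uniform missingness in the methylation-like layer.
Defaults: 3 × 40 samples, 1000 genes, modules of 60 genes at ρ = 0.8
(signature) and 0.4, δ = 2, expression layer (1 probe/gene, sd 0.5) and
methylation-like layer (2 probes/gene, sd 1.0, missing rate 0.002 — chosen
so that discarding any-missing probes removes ~20 %, not ~90 %, of
features). Class labels are scattered randomly over sample positions.

What passing on this generator shows: each stage recovers planted
structure (factors, informative kernels, modules, the signature) and the
statistics are calibrated under the null. What it does not show:
robustness to heavy-tailed noise, batch effects, beta-distributed
methylation marginals, copy-number segmentation, or correlated missingness
— none of which the generator models.

## Problem sizes and determinism

Default experiment sizes (120 samples, 1000 genes, ~160 fused genes, ranks
≤ 17, 10×10 CV) run the whole pipeline in a few seconds on one CPU; the
planted-recovery studies use matrices of a few dozen rows. Every stochastic
step takes an explicit integer seed, and derived seeds are simple offsets
of it, so whole-pipeline runs are bit-reproducible.

## Known limitations

* The relational-system construction fuses layers through gene membership
  and shared samples only; no cross-layer feature-feature relations.
* The MKL inner solve relies on libsvm's convergence; extremely
  ill-conditioned kernels can stall the outer backtracking early (the
  result is then the best iterate, still feasible).
* Cluster count is governed by `cut_height`/`min_module_size`, not chosen
  adaptively per branch; very nested module structure will be merged.
* CV metrics downstream of full-data screening are transductive, as
  discussed above.
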