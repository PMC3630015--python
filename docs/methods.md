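# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions, and the limitations of `paircorr`.  Everything
stated here is computed by the test suite or the acceptance script.

## Two-block projection fits

All fits operate on column-standardized matrices (mean 0, variance 1 with
ddof = 1, so the sample covariance of the standardized data *is* the
correlation matrix).  Zero-variance columns are rejected by name.

**PLS.**  Each dimension solves max cov(Xa, Yb) over unit-norm a, b by
alternating power iteration (NIPALS): a ∝ Xᵀv, b ∝ Yᵀu, iterated to a
loading change below 1e−9 (cap 500 iterations).  The iteration starts at
the leading right singular vector of XᵀY — the dense covariance maximizer
— which makes the per-dimension solution deterministic and, for sparse
fits, selects the dominant basin of the thresholded iteration rather than
an arbitrary one.  After each dimension both blocks are deflated by
regressing out a variate: regression mode removes the X-variate U from
both X and Y (asymmetric, X predicts Y); canonical mode removes U from X
and V from Y (symmetric).  Stored per dimension: loadings a, b; variates
U, V; their sds u_l, σ_l; regression coefficients φ (X on U) and ψ (Y on
U or V); ρ_l = cor(U_l, V_l); the Frobenius norm of the deflated Y.
Successive U variates are mutually orthogonal, which gives the exact
decomposition X = Σ U^l (φ^l)ᵀ at d = rank(X) and the identity
cor(Xʲ, U_l) = u_l φ_{jl} used as a test oracle.

**Sign convention.**  The largest-magnitude entry of each aˡ is made
positive and b, U, V flipped along with it, so identical inputs give
bit-identical fits (the underlying optimum is sign-ambiguous).

**Sparse PLS.**  The lasso penalty level is re-parametrized as the number
of variables to keep, per block and per dimension.  Inside each iteration
the unnormalized loading z is soft-thresholded at the midpoint between
the keep-th and (keep+1)-th largest |z| (ties broken by variable index),
leaving exactly `keep` nonzero entries, then renormalized.  With full
keep counts this reduces exactly to dense PLS.  Keep counts may vary per
dimension; matching them to expected group sizes makes each dimension
select one association group (verified on the generator at n = 500).

**CCA / ridge CCA.**  Canonical loadings come from the SVD of the
whitened cross-covariance L_x⁻¹ C_XY L_y⁻ᵀ, where L are Cholesky factors
of C_XX + λ₁I and C_YY + λ₂I (λ = 0 for classical CCA; regularizing the
covariance of standardized data is identical to regularizing the
correlation matrix).  Variates are rescaled to unit variance.  For
classical CCA the reported ρ_l are exactly cor(U_l, V_l); for ridge CCA
ρ_l are the singular values of the whitened problem — the conventional
"canonical values" of regularized CCA, shrunk below the empirical variate
correlation by the ridge (the empirical correlations remain available via
`ProjectionFit.variate_correlations()`; at λ = 0 the two definitions
coincide).  Classical CCA raises a singular-covariance error directing
the caller to `fit_rcca` when a block Cholesky fails.

**Ridge tuning.**  `tune_rcca` evaluates every (λ₁, λ₂) pair from a grid
(default 11 log-spaced points in [1e−3, 1]) by k-fold cross-validation
(default 5), scoring the mean held-out correlation of the first variate
pair; folds are a seeded permutation, ties keep the first pair in grid
order.  On strongly structured data the CV surface is nearly flat in λ, a
known property of ridge CCA; the function is therefore a convenience, not
a sharp selector.

## Variable coordinates and the similarity matrix

Coordinates are always computed as *empirical correlations* of each
variable with the reference axes (equiangular Z = U + V for the CCA
family; U, and U or V, for the PLS family), not from stored
coefficients — the closed forms u_lφ and σ_lψ serve as test oracles
instead.  Since the reference axes are mutually orthogonal, every
coordinate row has norm ≤ 1 (Bessel), hence |M| ≤ 1 entrywise for
M = x yᵀ.  M is oriented p × q (rows = X variables), following the
factorization order x (p × d), y (q × d).

For canonical-mode PLS the coordinate-based similarity equals
Σₗ u_l σ_l φ_{jl} ψ_{kl}.  A published variant weights the sum by
u_l²σ_l² instead; it is inconsistent with the coordinate definitions
above and is treated as a typographical slip — it remains available for
comparison via `pls_similarity_closed_form(..., printed_form=True)`.

For sparse fits, variables never selected on a retained dimension are
omitted from the coordinates and from M entirely (not zero-filled), so
their absence is explicit in every downstream view.

## Relevance networks

Edges are pairs with |M[j, k]| ≥ threshold; the boundary is inclusive so
printed thresholds like 0.5 keep exact ties.  The graph is strictly
bipartite and isolated variables are dropped.  Components are ordered by
their lexicographically smallest member.  GraphML export carries node
attribute `side` ∈ {X, Y} and edge attributes `weight` (float) and
`sign` ∈ {+, −}; SIF uses `pos`/`neg` interaction labels.  Raising the
threshold never adds edges or nodes.

## Clustered image map

Rows and columns of M are clustered independently: Euclidean distance +
Ward linkage by default.  "Ward" here means the ward.D2 convention — the
Lance–Williams recurrence on squared Euclidean distances with
square-rooted merge heights — the same convention scipy and R's
`hclust(method="ward.D2")` use on Euclidean input; an O(n³) re-scanning
oracle in the tests reproduces scipy's merge order and heights to 1e−10.
Leaf ordering is deterministic: within each merge the subtree with the
lower height is placed first, ties broken by smallest leaf index.  The
heatmap color scale is symmetric about zero and saturates at ±1 (red
negative, yellow weak, green positive) regardless of the empirical range,
so sign is always readable.

## Correlation circle plots

The plotted coordinates are exactly two columns of the similarity
coordinates — no recomputation — so circle, CIM and network views can
never disagree.  Points (dots for X, triangles for Y) lie in the unit
disk; guide circles at radii 0.5 and 1 are drawn; an optional threshold
hides points whose in-plane radius is below it without moving survivors.

## The synthetic-data generator

The generator emulates a two-block study with planted associations:
n = 30 samples; X groups A/B/C of 10/10/3 variables matched with Y
groups of 10/5/2; group A cross-correlations negative in [−0.93, −0.51],
group B positive in [0.5, 0.85], group C of mixed sign with magnitudes in
[0.81, 0.93] (positive to the first C-group Y variable, negative to the
second); 77 and 33 independent N(0,1) noise columns pad X to p = 100 and
Y to q = 50.  Draws are multivariate normal with unit variances,
Cholesky-factored, standardized, and labelled by group (`XA1`…, noise
columns prefixed `noise_`).

**Construction.**  Each matched group is driven by one shared latent
factor.  X-side loadings a_i and Y-side loadings b_k are spaced on a
square-root scale between √lo and √hi, so every cross-correlation
a_i·b_k lies inside [lo, hi] with the extreme magnitude attained exactly
at the largest pair (the A-block minimum is −0.93 exactly).  The
resulting correlation matrix is positive semi-definite *by construction*.
The tempting alternative — compound-symmetric within-blocks with
arbitrary values spread across the cross range — is far from PSD for
these ranges (smallest eigenvalue ≈ −1.05) and cannot be repaired without
distorting the targeted entries by ~0.5; it remains available as
`fill="linspace"` for mild ranges, with eigenvalue-clipping repair that
rejects any design whose targeted entries move by more than `repair_tol`
(default 0.02).  Within-group correlation is whatever the shared factor
induces (a_i·a_j, e.g. [0.51, 0.93] for group A); an optional
`within_corr` booster factor can raise it toward a target level where the
loadings leave room.

With this design the canonical-mode PLS latent correlations average
0.971 / 0.956 / 0.942 over dimensions 1–3 (20 seeds) before decaying,
and sparse PLS with per-dimension keep counts (10, 10, 3) / (10, 5, 2)
recovers each group exactly at n = 500.

**What the generator does not emulate.**  Real omics data are
non-Gaussian, heteroscedastic, and have correlated noise and batch
structure; passing tests on the generator demonstrate correctness of the
estimation and graphics machinery under the planted model, not robustness
to those artefacts.

## Known limitations

* **Ridge CCA canonical values are bounded by the block size.**  With
  10-variable groups, unit variances and λ = 0.889, the population first
  canonical value cannot exceed √(μ/(μ+λ)) ≤ √(10/10.889) ≈ 0.958 for
  any admissible covariance; replicate means on this design sit near
  0.91.  Single n = 30 draws scatter a few hundredths above and below.
* **Threshold-0.5 networks are noisy at n = 30.**  A variable's spurious
  correlation with an unrelated variate has sd ≈ 1/√29 ≈ 0.19; products
  with strong signal coordinates cross |M| = 0.5 with a few percent
  probability per pair, so single draws frequently show a handful of
  spurious edges (merged components, occasional noise variables).  This
  is a property of the estimator at that sample size — the sparse fits,
  larger n, or a higher threshold all mitigate it — and the test suite
  measures it rather than hiding it.
* Replicate counts (20 seeds) and the n = 500/5000 convergence checks
  were chosen so the full suite runs in seconds on one CPU.
* Interactive threshold exploration, within-block (X–X) networks, sample
  -space heatmaps and prediction of new samples are out of scope.
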