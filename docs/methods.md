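# Methods

## Model

`phenocell` treats phenotype-associated subpopulation discovery as a
penalized regression of bulk phenotypes on a sample × cell similarity
design. The design entry X[i, j] is the Pearson correlation, over the
genes shared by the two matrices after preprocessing, between bulk
sample i (log2 scale) and cell j (log-normalized scale). Cells enter
the model in groups — communities of the shared-nearest-neighbor (SNN)
cell graph found by Leiden optimization of the resolution-scaled
modularity

    Q = (1/2m) Σ_ij (A_ij − γ k_i k_j / 2m) δ(c_i, c_j)

with Jaccard edge weights A, weighted degrees k and total weight m
(the double sum runs over ordered pairs including i = j; A has no
self-loops). The coefficient vector β over cells minimizes

    (1/n) l(β) + λ [ (1−α) Σ_l √p_l ‖β^(l)‖₂ + α ‖β‖₁ ]

where p_l are group sizes. For a binary phenotype, l is the logistic
negative log-likelihood of the full linear predictor η_i = β₀ +
Σ_l x_i^(l)ᵀ β^(l) with an unpenalized intercept β₀. For survival, l
is the Breslow negative log partial likelihood with closed risk sets
R_i = {j : t_j ≥ t_i} and no intercept (absorbed by the baseline
hazard). Cells are classified by coefficient sign: positive ⇒
associated with the higher-encoded phenotype (case, worse survival),
negative ⇒ the lower-encoded one, exact zero (|β| ≤ 1e−12) ⇒
background.

Assumptions worth stating explicitly: cells in one transcriptional
community act as a unit with respect to the phenotype (that is what the
group penalty encodes); the bulk cohort and the single-cell atlas share
enough expression structure that gene-wise Pearson correlation is a
meaningful similarity; and the phenotype relates monotonically to the
abundance/activity of some subpopulations.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| γ (resolution) | 0.6 | modularity resolution; higher ⇒ more groups. A sweep {0.3 … 1.8} is exposed on the CLI |
| α grid | {0.005, 0.05, 0.1, 0.2, …, 0.8, 0.9, 0.95} | lasso/group-lasso mix candidates spanning both regimes |
| λ path | 20 log-spaced values, λ_max → 0.01·λ_max | λ_max computed per α by per-group root bracketing of the zero-solution subdifferential condition (tolerance 1e−10) |
| CV folds | 5, label-stratified in binary mode | |
| gene filter | expressed (count > 0) in ≥ 400 cells | appropriate for atlas-scale data (~1–2% of cells); synthetic runs use 10 of 500 cells, the same fraction |
| normalization | ln(1 + 10⁴·c/T) | library-size scale factor 10⁴; invariant to per-cell count rescaling |
| HVGs | top 2000 by standardized variance | variance-stabilizing scheme on raw counts, see below |
| PCA | 10 components, scaled values clipped at +10 | component signs fixed so the largest-magnitude loading is positive |
| SNN | k = 20 neighbors (self included), Jaccard weights, prune < 1/15 | |
| solver tol | 1e−5 (max coefficient change), KKT ≤ 10·tol | |

## Numerical choices

**Solver.** Blockwise descent over groups: each group is screened by
the exact group-zero condition ‖S_α(∇_l)‖₂ ≤ λ(1−α)√p_l (S_α =
soft-threshold at λα) and, if active, minimized by a monotone
accelerated proximal gradient method — FISTA steps accepted only when
the block objective decreases, otherwise a plain proximal step with
momentum restart, with backtracking line search on the smooth
majorization. Steps start at 1/L with L the spectral-norm Lipschitz
bound of the block. λ paths are warm-started downward. The logistic
intercept is updated by damped Newton each sweep. Convergence requires
both max |Δβ| < tol and max KKT residual ≤ 10·tol; non-convergence
raises an error carrying diagnostics. Kernels are numba-compiled; the
Cox loss uses cumulative log-sum-exp over time-sorted samples and
cannot overflow.

**Cross-validation.** Fold fits run at a relaxed tolerance (1e−3): the
held-out loss is a noisy estimate and does not benefit from final-fit
precision; the selected model is refit on all samples at full
tolerance. Held-out loss is the mean per-sample negative log-likelihood
(binary) or the Verweij–van Houwelingen contribution l_full(β) −
l_train(β) per held-out sample (survival). The selected pair applies
the one-standard-error rule: every (α, λ) whose mean loss is within one
SE of the minimizer counts as tied, and ties resolve toward larger λ,
then smaller α (sparser, more grouped models). The SE estimator follows
the loss structure: unpaired SE at the minimizer for the binary loss
(fold values are exchangeable per-sample means), fold-paired SE of the
difference against the minimizer for the survival deviance (fold values
carry a composition offset common to all pairs, which inflates the
unpaired SE several-fold and would otherwise make the band meaningless).
The exact minimizer is available via `selection="min"`. Folds that
leave a training part single-class (binary) or event-free (survival)
are redrawn, up to 100 attempts.

**HVG trend.** The mean–variance trend (log10 variance on log10 mean,
lowess span 0.3) must not chase the very genes it is meant to flag.
High-dispersion genes at the edge of the mean range have enough
leverage to pull a local fit through themselves, so a global Theil–Sen
line (no boundary leverage) first masks > 3-MAD outliers; the lowess
curve is fit on the remaining genes and interpolated to all. Ties in
the final ranking break lexicographically by gene ID.

**Degenerate inputs.** Zero-variance vectors in the correlation step
produce 0 entries with a logged warning (a constant cell carries no
association signal). Duplicate gene IDs are averaged (first-occurrence
order). A shared-gene set below 3 genes is an error at baseline and a
recorded degenerate row inside the robustness protocol. Coefficients
are computed on column-standardized X and returned on the original
scale; sign classification is invariant to this.

## Synthetic data

The generator emulates the data-generating assumptions of the model:
G cell groups each over-express a disjoint block of marker genes
(negative-binomial counts, dispersion 0.5, marker boost 6×, baseline
means Gamma-distributed around 2); bulk samples are Dirichlet convex
mixtures of the group programs with lognormal gene noise (sd 0.25) and
Poisson counting at fixed depth. In binary mode, case samples multiply
the planted group's mixture weight by the effect e (default 3) before
renormalization; the Dirichlet concentration is 30, i.e. the background
composition is stable across samples and the phenotype is the dominant
compositional signal — the regime in which a null cohort (e = 1) is
genuinely null. In survival mode the hazard is log-linear in the
sample's standardized planted weight (hazard ratio e per SD,
exponential baseline, uniform censoring window sized for roughly 30%
censoring); because the outcome tracks *natural* compositional
variation, survival cohorts use concentration 5.

What the generator does **not** emulate: real library-size variation
and gene-length effects, batch structure, overlapping or hierarchical
cell programs, ambient RNA/doublets, and dropout beyond NB sampling.
Passing recovery tests therefore demonstrates the machinery —
preprocessing, grouping, integration, selection — under the model's own
assumptions, not performance on any real cohort.

The robustness protocol re-runs the whole selection on shared-gene sets
restricted to bulk differentially expressed genes (Welch t-test, raw
p < 0.05, |log2 FC| above a threshold). Its synthetic check uses a
wider, stronger marker program (80 genes, boost 8, effect 5) and a
threshold grid calibrated to that data's fold-change scale, so that
every restricted set keeps the full signal block plus heterogeneous
context genes. A restriction to a *single homogeneous* block is a
structural blind spot of any correlation design — a uniform
multiplicative shift is removed by Pearson centering — and is not a
meaningful robustness probe.

## Design choices that were genuinely open

- Printed formulations of the two losses that sum the log-partition
  term per group are replaced by the standard negative log-likelihoods
  of the full linear predictor; the per-group form double-counts the
  partition function and is not a likelihood.
- "Survival time longer" is read as the closed risk set t_j ≥ t_i
  (universal Cox convention; the strict reading would exclude the
  failing sample from its own risk set).
- Correlations use all shared genes on log scale; the HVG set feeds
  only the embedding and graph.
- λ selection is automated as cross-validation with the 1-SE rule
  (above); fixed (α, λ) can be forced via `--fix-alpha/--fix-lambda`.
- The robustness protocol re-runs the full cross-validation per
  threshold (no parameter freezing) by default.

## Limitations

- The Pearson design is blind to phenotype effects that preserve the
  expression *pattern* over the chosen gene set (see above).
- Cross-validated selection on small cohorts (n ≲ 40) is noisy; the
  1-SE rule is conservative by construction and may select the empty
  model on weak signals.
- Near-collinear cell groups (e.g. two groups whose abundances are
  strongly anti-correlated across samples) can trade places in the
  fitted model; signs within the selected groups remain meaningful.
- Only flat partitions are supported (no multi-level communities), and
  only binary and survival phenotypes (no Gaussian loss).
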