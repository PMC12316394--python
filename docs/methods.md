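# Methods

## The estimand

For a two-condition Visium study, the quantity of interest is the power
of detecting a differentially expressed gene (DEG) inside an annotated
region of interest (ROI):

    Power_ROI(n, π_g, β_g, α, N)

where `n` is the number of ROI spots per slice, `N` the number of tissue
slices per group, `π_g` the gene's detection rate (fraction of spots with
a nonzero count, averaged over the two conditions), `β_g` its average
log₂ fold change, and `α` the desired Bonferroni-adjusted significance
level. Since `n` is fixed by the ROI in a given experiment, `N` is the
design variable.

## Bootstrap power estimation

The preliminary dataset's ROI spots, split by condition, are treated as
the population. One pseudo-experiment draws `n × N` spots per group
uniformly with replacement from that group's pool. Each pseudo-experiment
is log-normalized per spot (`ln(1 + 10⁴·count/library)`), and each gene
is tested with the two-sided Wilcoxon rank-sum test after a
`FindMarkers`-style prefilter: tested iff `max(pct1, pct2) ≥ min_pct`
(default 0.1) and `|avg log₂FC| ≥ 0.25`, where the fold change is
`log2((mean(expm1 x₁)+1)/(mean(expm1 x₂)+1))`. P-values are Bonferroni
multiplied by the *total* gene count of the dataset, mirroring the
`p_val_adj` convention of the DE tool this emulates. Power is the
fraction of the B repetitions (default 100) with adjusted p below α; a
repetition in which the gene failed the prefilter counts as
non-significant while the denominator stays B, so power is a multiple of
1/B and a gene that is rarely even evaluable is correctly penalized.
`π̂_g` and `|β̂_g|` are averaged over the repetitions where the gene was
evaluated; genes never evaluated are omitted from the power table (they
would carry no usable coordinates for the surface fit).

The rank-sum p-value uses the exact null distribution when both groups
are small and tie-free and otherwise the normal approximation with tie
and continuity corrections — the behaviour of R's `wilcox.test`, which
backs the DE tool being emulated. Bootstrap samples of realistic size
always contain ties, so the asymptotic path is the one exercised in
practice; the exact path matters only for the small-sample agreement
guarantees in the test suite.

Assumptions worth stating: (i) within the ROI, power is taken not to
depend on the spatial arrangement of spots, so resampling that destroys
the spatial configuration leaves power unchanged — the spatial character
of the data enters through the empirical spot-level distribution, not
through an imposed correlation model; (ii) batch effects are assumed
already removed; (iii) the preliminary pool is assumed representative of
the future population. Violations of (iii) show up as the small downward
bias visible in the oracle comparisons below (resampling a finite pool
carries slightly less information than fresh sampling).

A practical caveat surfaced by the synthetic experiments: per-spot
library normalization transmits strongly unbalanced DE to all other
genes (composition bias), so "null" genes in such a cohort sit above the
pure Bonferroni floor. This is a property of the normalization, not of
the power arithmetic.

## Monotone P-spline surfaces

For each N, the records `(π̂_g, |β̂_g|, power)` are smoothed by a
tensor-product quadratic B-spline surface constrained to be
non-decreasing in both coordinates. The constraint uses the
shape-constrained additive model (SCAM) reparameterization: with tensor
coefficients θ laid out on a q₁×q₂ grid,

    θ = (T₁ ⊗ T₂) e(γ),   e = [γ₁, exp(γ₂), …, exp(γ_p)],

where T are lower-triangular matrices of ones. Every forward difference
of θ along either grid axis is then a sum of exponentials, hence
non-negative, and a B-spline surface with coefficient grid non-decreasing
in both directions is itself non-decreasing in both inputs. The first
working parameter is the unconstrained surface level.

The objective is penalized least squares on the raw power values with
independent second-order difference penalties along the two axes of the
*working* parameter grid, weighted by λ₁ and λ₂. Difference rows that
touch the level coefficient are dropped: it carries power units while the
rest are log-increments, and coupling them biases increments away from
zero (this is also what lets a constant dataset be reproduced to ~1e-6).
A Gaussian likelihood on raw power with post-hoc clamping to [0, 1] is
used rather than a logit link because exactly-0 and exactly-1 power
values occur by construction (power is B-quantized).

Optimization is damped Newton–Raphson with analytic gradient and Hessian,
step-halving (≤30 halvings), relative-objective tolerance 1e-8, ≤200
iterations; when the full Newton direction fails to descend (the exp
reparameterization makes the problem non-convex), the Gauss–Newton
direction and finally normalized steepest descent are tried before
declaring a stationary point. (λ₁, λ₂) are selected by GCV,
`n·RSS/(n−edf)²` with edf from the working linear model at convergence,
over a log-spaced grid (default 10⁻⁴…10²), with warm starts across the
grid. Defaults q₁ = q₂ = 10 quadratic bases on equally spaced clamped
knots over the observed predictor ranges; fits are insensitive to q in
the 8–12 range because the shape constraint does most of the regularizing
work. Duplicate (π, β) points are kept and act as implicit weights.

One consequence of penalizing the working parameters: the penalty null
space consists of affine log-increment fields, which map to smoothly
*curved* monotone surfaces, not planes. So λ → ∞ yields the best fit in
that family rather than a flattened surface; the test suite checks the
limit via the monotone RSS-vs-λ trade-off instead of a range-shrinkage
argument.

Prediction clamps inputs to the fitted rectangle (flagging
extrapolation) and output to [0, 1]. Surfaces serialize to versioned
JSON; residual tables are exported because a nonparametric smoother can
leave structured residuals near the steep transition band, and those
should be inspected.

## Crossing detection and the boosted-tree remedy

Monotonicity in N is *not* enforced by the per-N spline fits. On a shared
evaluation grid (default 41×41 over the intersection of fitted ranges),
any cell where the surface for a larger N predicts strictly lower power
than that for a smaller N is flagged; the bounding box of flagged cells
is the recommended region for the 3D-monotone fallback. In practice
crossings concentrate where both π and |β| are near zero and the power
estimates themselves are noisy.

The fallback pools records over all N and fits gradient-boosted trees on
(π, |β|, N) with hard monotone-increasing constraints on all three
features (a candidate split that would violate monotonicity is never
accepted, so the constraint is exact, at the cost of a step-function
fit). Records are filtered to the region and split 80/10/10
train/validation/test with a seeded permutation; depth ∈ {2…6} × learning
rate ∈ {0.05, 0.1, 0.3} are chosen by validation RMSE with early
stopping (≤500 trees, patience 20); the test RMSE is computed once, after
selection. N is treated as a numeric feature (ordering is what the
constraint needs). The default backend is XGBoost; LightGBM with
equivalent settings serves as an independent cross-check, and the
comparison report (grid max/mean |Δ|, feature importances) is produced by
`crosscheck_backends`. Whole-surface tree fits are deliberately not
offered as the primary estimator — the step-function character makes
them crude where power rises steeply — which is why the region defaults
to the crossing bounding box.

## Synthetic data generator and what it does (not) show

The generator emulates a two-condition Visium cohort: genes × spots
negative-binomial counts in the mean/size parameterization
(`var = μ + μ²/size`), slices of ~80 spots on a hexagonal grid with
100-unit center spacing, a designated DEG block whose condition-2 mean is
`baseline·2^logFC`, per-gene extra Bernoulli dropout to control detection
rates, and an optional zero-mean squared-exponential Gaussian-process
log-mean field over spot coordinates (marginal SD 0.5 by default,
mean-corrected so gene means are exact) for within-slice spatial
autocorrelation. Defaults — 80 spots per slice ROI, baseline mean 2,
dispersion (size) 2 — describe a moderately expressed gene panel at
Visium-like depth. Everything is reproducible bit-for-bit from the
design seed.

The companion `true_power_oracle` draws fresh cohorts from the generative
model (no bootstrap), runs the identical normalization, prefilter and
test on the target gene, and returns the rejection fraction — an
independent standard the bootstrap estimator is compared against in the
acceptance tests (agreement within ±0.12 across a 3×3 effect-size ×
abundance grid at B = 50, oracle reps = 200; the residual gap is
dominated by finite-pool bias, not by the power arithmetic).

What the generator does not emulate: real tissue morphology, cell-type
mixture within spots, gene–gene correlation, or the zero-inflation
patterns of real Visium ROIs in which lowly detected genes can carry
large conditional effects. Consequently, passing synthetic tests
demonstrates the correctness and calibration of the machinery, not that
any particular real tissue will show the same power at the same
(π, |β|, N) — for that, the bootstrap must be run on the user's own
preliminary data.

## Problem sizes used in the checks

The acceptance-style checks run at deliberately desk-sized scales chosen
to keep Monte-Carlo error well inside the stated tolerances: null
calibration at 1,000 genes × B = 50; power recovery at 200 genes ×
B = 50 vs 200 oracle replications per stratum; surface fits on 500-point
synthetic truths and on ~300-gene bootstrap cohorts at N ∈ {4, 6, 8}.
The method itself has no scale limit beyond runtime: B and the gene count
enter linearly.

## Known limitations

- The bootstrap inherits the preliminary pool: pools much smaller than
  the resampled pseudo-experiments (e.g. 2–3 slices per arm) increase
  both bias and repetition-to-repetition correlation of the estimates.
- Power at the prefilter boundary (|β| ≈ 0.25) is discontinuous by
  construction; the monotone smooth necessarily rounds that cliff, which
  is where in-sample residuals concentrate.
- GCV can undersmooth when records cluster at power 0/1; the exported
  residual tables are the diagnostic.
- The GBT remedy guarantees monotonicity, not smoothness; its
  predictions are steps and should be read locally.
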