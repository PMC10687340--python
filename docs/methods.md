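# Methods

## Scope and data model

`lfqbayes` operates on a feature × sample matrix of label-free MS
abundances with a condition label per sample. Preprocessing divides each
sample by a median-of-ratios scale factor — the median over complete rows of
the measurement divided by the row's geometric mean across samples — and
log2-transforms. Only rows without missing values contribute to the scale
factors; rows that still contain missing values after normalization are
dropped by default (imputation is deliberately out of scope; the
`drop_missing=False` hook passes incomplete rows through for external
tools). Note that this normalization is equivariant to per-sample rescaling
only up to a global additive log2 constant, because the row geometric mean
includes every sample; all downstream quantities (contrasts of condition
means, SDs) are invariant to that constant.

Per-feature summaries are the mean and the sample SD (n−1 denominator)
pooled over **all** samples of the feature, not per condition: the trend
models describe one mean and one SD per feature. Features with zero SD are
excluded from trend fitting but can still be tested, with their uncertainty
evaluated from the trend at their mean.

## Mean–variance trend models

**Gamma regression (GR).** Sample SDs are gamma with a log-link mean,
`E[s_i] = exp(g0 + gy*ybar_i)`. The fit is the standard IRLS gamma GLM
(statsmodels); the shape estimate is the inverse Pearson dispersion,
`df_resid / pearson_chi2`, matching the GLM-summary convention of the
R ecosystem. Tests verify the IRLS optimum against a generic Nelder–Mead
maximizer of the gamma log-likelihood (for a log link the mean-parameter
optimum is shape-free, so the reference minimizes `sum(log mu + s/mu)`).
The gamma prior on a feature's SD uses `alpha = shape` and
`beta_i = shape / exp(g0 + gy*ybar_i)`, so the prior mean equals the
trend's expected SD at the feature's mean — the same expression used for
the per-measurement uncertainty `u_ij = exp(g0 + gy*y_ij)`.

**Latent gamma mixture regression (LGMR).** The expected SD mixes a common
and a latent exponential trend on standardized means
`f(x) = (x − mean(ybar)) / sd(ybar)`:

    E[s_i] = exp(g0 − gy f(ybar_i)) + kappa · exp(theta_i (g0L − gyL f(ybar_i)))

`kappa` (default 0.001) bounds the latent trend's minimal contribution;
`theta_i ∈ [0,1]` is each feature's share of the latent trend. Slopes enter
with a minus sign and are constrained non-negative, so the trend never
increases with abundance. Priors: `alpha ~ Half-Cauchy(25)`,
`g0 ~ N(0,1)`, `theta_i ~ U(0,1)`, slopes `~ Half-Normal(1)`, and the
latent intercept `g0L ~ Skew-Normal(location 1, scale 15, shape 30)` — a
weak right-skewed prior with a small positive location that offsets the
shrinkage by `kappa`. The slope scale and the skew-normal hyperparameters
are package defaults exposed in `LGMRConfig`, chosen as the weakest settings
that keep the latent intercept right-skewed and the slopes order-one;
they are deliberately configurable because no stronger external convention
exists. Point estimates for downstream use are posterior means, including
per-feature `theta`. The goodness-of-fit NRMSE
(`sqrt(mean((s−mu)^2)/Var(s))`) is computed per posterior draw with the
draw's `mu_i` and averaged — a posterior-mean NRMSE, slightly conservative
relative to a plug-in estimate. The standardizer is frozen from the
fitting-stage means and reused for all predictions, including when the
trend is evaluated at individual measurements `y_ij`. Features absent from
the fit (zero SD) fall back to `theta = 0`, the common trend.

## Posterior computation

No Stan-style sampler ships with the scientific Python stack this package
targets, so inference uses the package's own No-U-Turn sampler: multinomial
NUTS with tree doubling, slice-free biased progressive sampling, Nesterov
dual averaging of the step size toward a target acceptance statistic
(0.9 for LGMR, 0.8 for the decision model), and a diagonal mass matrix
estimated in Stan-style expanding warmup windows. Divergences are declared
at an energy error of 1000; gradients are analytic for both models (the
decision-model kernel is numba-compiled; the LGMR kernel is vectorized
numpy). The sampler is validated against closed-form posteriors and scipy
reference distributions, and both models' gradients against finite
differences. Constrained parameters are sampled on unconstrained scales
(log for positive, logit for `theta`) with Jacobian corrections.

Defaults follow common practice for this model family: LGMR uses 5 chains
× (500 warmup + 2000 draws), the decision model 4 chains × (1000 + 1000)
per feature. Tests and the acceptance script use 2 chains and a few hundred
draws per stage — sufficient for the point estimates and interval checks
they make — and state their problem sizes explicitly.

## Decision model

Measurement noise is `sigma * u_n`; condition means use the expanded
non-centered parameterization `mu_c = mu0_c + eta_c*sigma + sigma*z_c` with
standard-normal `eta, z`, which keeps the group-level effect proportional
to `sigma` and improves sampling geometry. The variance prior
`sigma ~ Gamma(alpha, beta_i)` comes from the trend. The EB mean prior is
centered at the condition sample means with SD `sigma*sqrt(2/n_c)` ("twice
the common variance over the replicate count"); the WI prior is `N(0, 10)`.

Contrast columns must sum to zero with positive parts summing to one and
absolute sum two; the contrast-weighted sample size is
`xi_m = sum_c |k_cm| / n_c`. The decision statistic `D_m` is drawn once per
posterior draw as `N(mu'k_m, sigma*g(xi_m))`. The default scale map is the
literal `g(xi) = xi`; `g(xi) = sqrt(xi)` — the sampling-theory standard
error for a pairwise contrast — is available via `DecisionConfig.scale_map`
because the two conventions genuinely differ (for `n_c = 4` pairwise,
`xi = 0.5 < sqrt(0.5)`, so the literal form gives tighter decisions). The
error probability `2*Phi(−|mean(D) − mu_h0| / sd(D))` uses the sample mean
and SD of the posterior draws of `D`; `mu_h0` defaults to 0 and is
configurable per contrast. Error probabilities are reported raw — no
multiplicity adjustment — while the t-test comparator is BH-adjusted within
each comparison, mirroring how the two are used in practice.

Features are processed independently with per-feature seeds spawned from
the global seed and the feature index (`numpy.random.SeedSequence`), so the
result table is identical for any worker count and fully reproducible from
the manifest. Per-feature sampler failures are recorded in the `message`
column and do not abort the run. R-hat above 1.05 on `sigma` or any `D`
flags the feature.

## Synthetic benchmark generator

The generator emulates a two-condition spike-in experiment on the log2
scale: grand means uniform over (14, 22) (typical normalized log2
intensities), per-feature expected SDs from the latent-mixture trend with
defaults `g0 = −0.7, gy = 0.35, g0L = 4, gyL = 1, kappa = 0.001,
shape = 3` — SDs around 0.3–0.8 log2 units that shrink with abundance plus
a latent high-variance component at low abundance — `theta ~ U(0,1)`,
realized SDs gamma around the trend, 4 replicates per condition, 10%
spike-ins at 1 log2-unit fold change split symmetrically across the two
contrasted conditions. What it does **not** emulate: missing values,
peptide-to-protein hierarchy, correlated features, non-normal measurement
error, or batch structure. Passing tests therefore demonstrate internal
consistency and calibrated behavior under the model's assumptions, not
performance on any particular instrument's output.

Mixture-regression comparison tests use a pronounced latent component
(`g0L = 5.5, gyL = 1.5`) because the advantage of the mixture over the
single trend is only identifiable when the data actually contain a latent
trend; with the generator's mild defaults the two models fit equally well
and the comparison is uninformative.

## Evaluation harness

Decisions are swept over 1112 evenly spaced thresholds on the closed
interval [−0.1, 1], so curves start at the origin (no error probability is
≤ −0.1). TPR/FPR/precision/MCC use the standard confusion-count formulas;
MCC is defined as 0 when any marginal is zero, and precision is reported
missing when no positives are called. auROC integrates TPR over FPR by the
trapezoid rule along the sweep; it is invariant to monotone score
transformations only up to grid resolution (~1e-3). The t-test baseline is
the pooled-variance two-sample t test per pairwise contrast with BH
adjustment. The power harness subsamples replicates without replacement
within condition (24 combinations per size by default, one deterministic
evaluation when the size uses every replicate) and reports mean ± SEM of
TP and FP per method.

## Numerical choices and limitations

* IRLS convergence: statsmodels defaults with tolerance 1e-10, 100
  iterations; degenerate (constant-mean) covariates are rejected.
* NUTS: max tree depth 10; initial step size by the doubling heuristic;
  mass-matrix regularization shrinks window variances toward 1e-3.
* LGMR likelihood guards: non-finite mixture means reject the proposal
  rather than propagating NaN.
* The decision model assumes complete data, a single condition factor, and
  zero covariance between measurements; covariate adjustment and
  missing-data modeling are out of scope.
* The EB prior conditions on the jointly sampled `sigma` (no plug-in).
* Contrast validation tolerance is 1e-9 on the column constraints.
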