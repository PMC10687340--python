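# lfqbayes

Bayesian differential-abundance testing for label-free quantitative
proteomics (peptides, proteins, or PTM sites), built around explicit
modeling of the data's mean–variance trend.

## The problem

Label-free MS quantification is noisy, and the noise is not uniform:
low-abundance features have systematically larger relative variability.
Classical per-feature t tests ignore this structure; moderation methods
borrow a global variance trend. `lfqbayes` estimates the local
mean–variance (M–V) trend, converts it into per-measurement uncertainties
and into a prior for each feature's variance, and then tests contrasts
between conditions with a per-feature Bayesian hierarchical model that
returns a *probability of error* rather than a p-value.

## The model

For one feature with `N` log2 measurements `Y`, design matrix `X`
(conditions `c = 1..C` with `n_c` replicates) and trend-predicted
uncertainty multipliers `u`:

    Y     ~ N(X mu, sigma * u)
    mu_c  ~ N(mu0_c + eta_c * sigma, sigma),   eta_c ~ N(0, 1)
    sigma ~ Gamma(alpha, beta)

with either an empirical-Bayes prior `mu0_c ~ N(ybar_c, sigma*sqrt(2/n_c))`
or a weakly informative `mu0_c ~ N(0, 10)`. For each contrast column `k_m`
(zero-sum, positive weights summing to one) the decision statistic

    D_m ~ N(mu' k_m,  sigma * xi_m),   xi_m = sum_c |k_cm| / n_c

is drawn per posterior draw and the error probability is the two-sided tail
mass `2 * Phi(-|mean(D) - mu_h0| / sd(D))`.

The hyperparameters `alpha, beta` and the uncertainties `u` come from one of
two M–V trend models fitted to the per-feature sample means and SDs:

* **GR** — a gamma GLM with log link, `E[s] = exp(g0 + gy*ybar)`, fitted by
  IRLS; the shape is the inverse Pearson dispersion.
* **LGMR** — a latent gamma mixture regression,
  `E[s_i] = exp(g0 - gy*f(ybar_i)) + kappa * exp(theta_i*(g0L - gyL*f(ybar_i)))`,
  where `f` standardizes the means, `theta_i` in [0,1] is a per-feature
  latent mixing weight, and slopes are constrained non-negative so noise
  never grows with abundance. Fitted by a built-in No-U-Turn sampler.

A synthetic spike-in generator, confusion/ROC/MCC scoring, a pooled-variance
t-test baseline and a replicate-subsampling power harness make the whole
pipeline testable without external data.

## Worked example

```sh
python examples/03_differential_abundance.py
```

simulates 120 features (12 spike-ins at 1 log2-unit fold change, 2x4
samples), fits the GR trend and tests one contrast. Output:

```
features called at err <= 0.05: 12 of 120
   feature    lfc_0        err_0
peptide_22 1.079238 2.523828e-19
peptide_75 1.143506 1.152641e-03
peptide_73 1.853847 1.281906e-03
peptide_32 1.291915 5.161815e-03
peptide_94 1.084205 9.794381e-03
...

vs truth at 5%: TPR 0.67  FPR 0.037  precision 0.67  MCC 0.63
auROC: 0.884
pooled t test (BH) at 5%: TPR 0.17  FPR 0.000
```

Eight of the twelve spike-ins are recovered at a 3.7% false-positive rate,
four times the recall of the BH-adjusted pooled t test at the same
significance level. The estimated `lfc` of the true calls clusters around
the simulated fold change of 1. The other examples demonstrate
normalization plus trend fitting, the latent mixture regression, and the
power analysis.

The same pipeline is scriptable from the shell:

```sh
lfqbayes simulate --p 500 --seed 7 --out-prefix sim
lfqbayes test sim.tsv sim_design.tsv --contrasts contrasts.tsv \
    --trend lgmr --prior eb --seed 7 --already-log2
lfqbayes evaluate lfqbayes_out/results.tsv sim_truth.tsv
```

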