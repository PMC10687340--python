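import numpy as np
import pytest
from scipy import stats as sps

from lfqbayes.decision import (
    DecisionConfig,
    PeptideModelInput,
    build_mean_prior,
    design_from_conditions,
    p_error,
    run_all,
    sample_peptide,
    validate_contrasts,
)
from lfqbayes.gamma_trend import GRFit
from lfqbayes.synthetic import SimulationSpec, simulate

FAST = DecisionConfig(chains=2, warmup=400, draws=600, seed=0)


def two_group_input(y, u=None, alpha=2.0, beta=4.0):
    y = np.asarray(y, dtype=float)
    n = y.size // 2
    return PeptideModelInput(
        y=y,
        u=np.ones_like(y) if u is None else np.asarray(u, dtype=float),
        alpha=alpha,
        beta=beta,
        ybar_c=np.array([y[:n].mean(), y[n:].mean()]),
    )


class TestContrasts:
    def test_pairwise_contrast_weighted_size(self):
        spec = validate_contrasts(np.array([[1.0], [-1.0]]), np.array([4, 4]))
        np.testing.assert_allclose(spec.xi, [0.5])

    def test_nonpairwise_contrast(self):
        spec = validate_contrasts(np.array([[-0.5], [1.0], [-0.5]]), np.array([3, 3, 3]))
        np.testing.assert_allclose(spec.xi, [2 / 3])

    def test_nonzero_column_sum_rejected(self):
        with pytest.raises(ValueError, match="sum.*!= 0"):
            validate_contrasts(np.array([[1.0], [1.0]]), np.array([3, 3]))

    def test_positive_sum_constraint(self):
        with pytest.raises(ValueError):
            validate_contrasts(np.array([[2.0], [-2.0]]), np.array([3, 3]))

    def test_empty_contrasts_rejected(self):
        with pytest.raises(ValueError, match="no contrasts"):
            validate_contrasts(np.empty((2, 0)), np.array([3, 3]))


class TestMeanPrior:
    def test_wi_is_wide_zero_centered(self):
        prior = build_mean_prior("wi", np.array([5.0, 6.0]), np.array([4, 4]))
        np.testing.assert_allclose(prior["center"], 0.0)
        assert prior["sd"] == 10.0

    def test_eb_sd_multiplier(self):
        prior = build_mean_prior("eb", np.array([5.0, 6.0]), np.array([4, 4]))
        np.testing.assert_allclose(prior["sd_mult"], np.sqrt(0.5))
        np.testing.assert_allclose(prior["center"], [5.0, 6.0])

    def test_eb_prior_shrinks_with_replicates(self):
        small = build_mean_prior("eb", np.zeros(1), np.array([4]))["sd_mult"][0]
        large = build_mean_prior("eb", np.zeros(1), np.array([4000]))["sd_mult"][0]
        assert large < small / 10


class TestPError:
    def test_no_difference_gives_one(self):
        assert p_error(1.3, 0.5, 1.3) == 1.0

    def test_standard_normal_quantile(self):
        np.testing.assert_allclose(p_error(1.959964, 1.0, 0.0), 0.05, atol=1e-6)

    def test_monotone_decreasing_in_distance(self):
        vals = [p_error(d, 1.0) for d in np.linspace(0, 5, 11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            p_error(1.0, 0.0)


class TestSamplePeptide:
    def test_well_separated_groups(self):
        rng = np.random.default_rng(2)
        y = np.r_[rng.normal(0, 0.1, 4), rng.normal(3, 0.1, 4)]
        design = design_from_conditions(["a"] * 4 + ["b"] * 4)
        K = validate_contrasts(np.array([[1.0], [-1.0]]), design.n)
        res = sample_peptide(two_group_input(y), design, K, "wi", FAST)
        # with a weak prior the posterior mean of D tracks the observed
        # difference of sample means (contrast sign convention: a - b)
        sample_diff = y[:4].mean() - y[4:].mean()
        assert abs(res.lfc[0] - sample_diff) < 0.1
        assert abs(abs(res.lfc[0]) - 3.0) < 0.35
        assert res.err[0] < 1e-3

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(3)
        half = rng.normal(1.0, 0.3, 4)
        design = design_from_conditions(["a"] * 4 + ["b"] * 4)
        K = validate_contrasts(np.array([[1.0], [-1.0]]), design.n)
        res = sample_peptide(two_group_input(np.r_[half, half]), design, K, "eb", FAST)
        assert abs(res.lfc[0]) < 0.1
        assert res.err[0] > 0.8

    def test_posterior_sd_near_sampling_theory_limit(self):
        # large n, diffuse sigma prior: posterior SD of each condition mean
        # approaches the frequentist standard error
        rng = np.random.default_rng(4)
        n = 60
        y = np.r_[rng.normal(0, 1, n), rng.normal(0, 1, n)]
        design = design_from_conditions(["a"] * n + ["b"] * n)
        K = validate_contrasts(np.array([[1.0], [-1.0]]), design.n)
        inp = PeptideModelInput(y=y, u=np.ones(2 * n), alpha=0.01, beta=0.01,
                                ybar_c=np.array([y[:n].mean(), y[n:].mean()]))
        res = sample_peptide(inp, design, K, "wi", FAST)
        se = y[:n].std(ddof=1) / np.sqrt(n)
        post_sd = (res.summaries["mu[a]"]["q975"] - res.summaries["mu[a]"]["q025"]) / (2 * 1.96)
        assert abs(post_sd - se) / se < 0.15

    def test_negated_contrast_flips_lfc_keeps_err(self):
        rng = np.random.default_rng(5)
        y = np.r_[rng.normal(0, 0.3, 4), rng.normal(0.8, 0.3, 4)]
        design = design_from_conditions(["a"] * 4 + ["b"] * 4)
        K2 = validate_contrasts(np.array([[1.0, -1.0], [-1.0, 1.0]]), design.n)
        res = sample_peptide(two_group_input(y), design, K2, "eb", FAST)
        assert abs(res.lfc[0] + res.lfc[1]) < 0.05
        assert abs(res.err[0] - res.err[1]) < 0.02

    def test_scale_map_options_change_decision_spread(self):
        rng = np.random.default_rng(6)
        y = np.r_[rng.normal(0, 0.3, 4), rng.normal(1, 0.3, 4)]
        design = design_from_conditions(["a"] * 4 + ["b"] * 4)
        K = validate_contrasts(np.array([[1.0], [-1.0]]), design.n)
        lit = sample_peptide(two_group_input(y), design, K, "eb", FAST)
        sqrt_cfg = DecisionConfig(chains=2, warmup=400, draws=600, seed=0, scale_map="sqrt_xi")
        sq = sample_peptide(two_group_input(y), design, K, "eb", sqrt_cfg)
        # xi = 0.5 < sqrt(0.5), so the literal scale gives a tighter D
        lit_sd = lit.summaries["D[0]"]["q975"] - lit.summaries["D[0]"]["q025"]
        sq_sd = sq.summaries["D[0]"]["q975"] - sq.summaries["D[0]"]["q025"]
        assert lit_sd < sq_sd


@pytest.fixture(scope="module")
def small_dataset():
    ds = simulate(SimulationSpec(p=12, seed=9, spike_fraction=0.25))
    trend = GRFit(gamma0=-0.7, gamma_ybar=0.0, shape=3.0, nrmse=0.5)
    return ds, trend


class TestRunAll:
    def test_worker_count_invariance(self, small_dataset):
        ds, trend = small_dataset
        K = np.array([[1.0], [-1.0]])
        cfg1 = DecisionConfig(chains=2, warmup=200, draws=300, seed=7, workers=1)
        cfg4 = DecisionConfig(chains=2, warmup=200, draws=300, seed=7, workers=4)
        r1 = run_all(ds.matrix, trend, K=K, cfg=cfg1)
        r4 = run_all(ds.matrix, trend, K=K, cfg=cfg4)
        assert r1.equals(r4)

    def test_detects_spikes_and_reports_columns(self, small_dataset):
        ds, trend = small_dataset
        K = np.array([[1.0], [-1.0]])
        cfg = DecisionConfig(chains=2, warmup=300, draws=400, seed=8)
        res = run_all(ds.matrix, trend, K=K, cfg=cfg)
        assert set(res.columns) >= {"feature", "lfc_0", "err_0", "sigma_mean", "flagged"}
        spike_err = res["err_0"].to_numpy()[ds.truth]
        null_err = res["err_0"].to_numpy()[~ds.truth]
        assert spike_err.max() < np.median(null_err)

    def test_missing_contrasts_rejected(self, small_dataset):
        ds, trend = small_dataset
        with pytest.raises(ValueError, match="no contrasts"):
            run_all(ds.matrix, trend, K=None)

    def test_power_concentrates_at_low_predicted_sd(self):
        # spike-ins whose trend-predicted SD is below the median are detected
        # far more often than the noisier half (pooled over two datasets)
        from lfqbayes.gamma_trend import fit_gr, predict_uncertainty_gr
        from lfqbayes.preprocess import summarize_peptides

        hits = {"low": [], "high": []}
        for seed in (60, 61):
            ds = simulate(SimulationSpec(p=100, replicates=4, spike_fraction=0.5,
                                         lfc=1.0, seed=seed))
            stats = summarize_peptides(ds.matrix)
            trend = fit_gr(stats)
            res = run_all(ds.matrix, trend, K=np.array([[1.0], [-1.0]]), prior="eb",
                          cfg=DecisionConfig(chains=2, warmup=300, draws=500, seed=1))
            errs = res["err_0"].to_numpy()
            low = predict_uncertainty_gr(trend, stats.ybar) < np.median(
                predict_uncertainty_gr(trend, stats.ybar))
            hits["low"].extend(errs[ds.truth & low] <= 0.05)
            hits["high"].extend(errs[ds.truth & ~low] <= 0.05)
        tpr_low = np.mean(hits["low"])
        tpr_high = np.mean(hits["high"])
        assert tpr_low > tpr_high
        assert tpr_low > 0.7
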