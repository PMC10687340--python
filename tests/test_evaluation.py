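import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lfqbayes.decision import design_from_conditions, validate_contrasts
from lfqbayes.evaluation import (
    ConfusionCounts,
    confusion_at,
    metrics,
    power_experiment,
    roc,
    t_test_baseline,
)
from lfqbayes.synthetic import SimulationSpec, simulate

from conftest import make_normalized


class TestConfusion:
    def test_enumeration_example(self):
        c = confusion_at(np.array([0.01, 0.2, 0.04]), np.array([True, False, True]), 0.05)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 1, 0)

    def test_sweep_endpoints(self):
        scores = np.array([0.2, 0.9, 0.5])
        truth = np.array([True, False, True])
        low = confusion_at(scores, truth, -0.1)
        assert low.tp == low.fp == 0
        high = confusion_at(scores, truth, 1.0)
        assert high.fn == high.tn == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_at(np.array([]), np.array([], dtype=bool), 0.05)


class TestMetrics:
    def test_mcc_hand_computation(self):
        got = metrics(ConfusionCounts(tp=3, tn=90, fp=7, fn=0))[3]
        expected = (3 * 90 - 7 * 0) / np.sqrt(3 * 10 * 90 * 97)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_perfect_classifier(self):
        tpr, fpr, prec, mcc = metrics(ConfusionCounts(tp=5, tn=20, fp=0, fn=0))
        assert (tpr, fpr, prec, mcc) == (1.0, 0.0, 1.0, 1.0)

    def test_half_recall(self):
        tpr = metrics(ConfusionCounts(tp=4, tn=1, fp=1, fn=4))[0]
        assert tpr == 0.5

    def test_zero_marginal_gives_zero_mcc(self):
        assert metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))[3] == 0.0

    @given(st.tuples(*[st.integers(min_value=0, max_value=500)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        got = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        tpr = tp / (tp + fn) if tp + fn else np.nan
        fpr = fp / (fp + tn) if fp + tn else np.nan
        prec = tp / (tp + fp) if tp + fp else np.nan
        denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
        mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
        for g, e in zip(got, (tpr, fpr, prec, mcc)):
            assert (np.isnan(g) and np.isnan(e)) or abs(g - e) < 1e-12
        assert -1 - 1e-12 <= got[3] <= 1 + 1e-12


class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.full(10, 0.01), np.full(40, 0.9)]
        truth = np.r_[np.ones(10, bool), np.zeros(40, bool)]
        curve = roc(scores, truth)
        np.testing.assert_allclose(curve.auroc, 1.0)
        assert curve.tpr[0] == 0.0 and curve.fpr[0] == 0.0  # origin at -0.1

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 4000)
        truth = rng.random(4000) < 0.5
        assert abs(roc(scores, truth).auroc - 0.5) < 0.05

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 300)
        truth = rng.random(300) < 0.3
        a = roc(scores, truth).auroc
        b = roc(scores**3, truth).auroc  # strictly monotone on [0, 1]
        # invariant up to the resolution of the fixed threshold grid
        np.testing.assert_allclose(a, b, atol=0.005)

    def test_score_reversal_complements_auroc(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 1, 500)
        truth = scores + rng.normal(0, 0.3, 500) < 0.4
        a = roc(scores, truth).auroc
        b = roc(1.0 - scores, truth).auroc
        np.testing.assert_allclose(a + b, 1.0, atol=0.02)

    def test_grid_must_cover_interval(self):
        with pytest.raises(ValueError, match="grid"):
            roc(np.array([0.5]), np.array([True]), grid=np.linspace(0, 0.5, 10))


class TestTTestBaseline:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 1, size=(20, 8))
        nm = make_normalized(vals, ["A"] * 4 + ["B"] * 4)
        design = design_from_conditions(["A"] * 4 + ["B"] * 4)
        K = validate_contrasts(np.array([[1.0], [-1.0]]), design.n)
        out = t_test_baseline(nm, design, K)
        ref = sps.ttest_ind(vals[:, :4], vals[:, 4:], axis=1, equal_var=True).pvalue
        np.testing.assert_allclose(out["p_0"], ref, rtol=1e-12)

    def test_bh_step_up_rule(self):
        # adjusted p for (0.01, 0.02, 0.03, 0.04) with m=4 is 0.04 throughout
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)

    def test_identical_groups_never_significant(self):
        rng = np.random.default_rng(4)
        half = rng.normal(12, 1, size=(15, 3))
        nm = make_normalized(np.hstack([half, half]), ["A"] * 3 + ["B"] * 3)
        design = design_from_conditions(["A"] * 3 + ["B"] * 3)
        K = validate_contrasts(np.array([[1.0], [-1.0]]), design.n)
        out = t_test_baseline(nm, design, K)
        assert (out["padj_0"] > 0.99).all()

    def test_nonpairwise_contrast_rejected(self):
        nm = make_normalized(np.ones((3, 9)), ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        design = design_from_conditions(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        K = validate_contrasts(np.array([[1.0], [-0.5], [-0.5]]), design.n)
        with pytest.raises(ValueError, match="pairwise"):
            t_test_baseline(nm, design, K)


class TestPowerExperiment:
    def make_methods(self):
        def ttest(sub):
            design = design_from_conditions(
                [sub.condition_of_sample[s] for s in sub.sample_ids]
            )
            K = validate_contrasts(np.array([[1.0], [-1.0]]), design.n)
            return t_test_baseline(sub, design, K)["padj_0"].to_numpy()

        return {"t_test": ttest}

    def test_full_size_is_deterministic_point(self):
        ds = simulate(SimulationSpec(p=50, replicates=4, seed=5))
        table = power_experiment(ds.matrix, ds.truth, self.make_methods(), [4], seed=1)
        assert table["n_combos"].tolist() == [1]
        assert table["tp_sem"].tolist() == [0.0]

    def test_tp_nondecreasing_with_replicates(self):
        ds = simulate(SimulationSpec(p=120, replicates=8, lfc=1.2, seed=6))
        table = power_experiment(
            ds.matrix, ds.truth, self.make_methods(), [3, 5, 8], combos_per_size=8, seed=2
        )
        tp = table.sort_values("size")["tp_mean"].to_numpy()
        assert tp[0] <= tp[1] + 1e-9 <= tp[2] + 1e-9

    def test_oversized_request_rejected(self):
        ds = simulate(SimulationSpec(p=20, replicates=3, seed=7))
        with pytest.raises(ValueError, match="exceeds"):
            power_experiment(ds.matrix, ds.truth, self.make_methods(), [5])
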