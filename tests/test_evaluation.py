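import numpy as np
import pytest
from scipy import stats

import neurosem as ns
from neurosem.evaluate import SeparationError


class TestLogisticFitAic:
    def test_null_model_closed_form_aic(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        fit = ns.logistic_fit_aic(np.empty((100, 0)), y)
        assert fit.aic == pytest.approx(2 - 2 * 100 * np.log(0.5), rel=1e-6)

    def test_feature_equal_to_outcome_is_separation(self):
        y = np.r_[np.zeros(30), np.ones(30)]
        with pytest.raises(SeparationError):
            ns.logistic_fit_aic(y.copy(), y)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(SeparationError):
            ns.logistic_fit_aic(np.zeros((20, 1)), np.ones(20))

    def test_null_wald_p_is_uniform(self, rng):
        pvals = []
        y = np.r_[np.zeros(50), np.ones(50)]
        for _ in range(1000):
            pvals.append(ns.logistic_fit_aic(rng.normal(size=(100, 1)), y).pvalues[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCombineSnpScores:
    def test_max_then_min_example(self):
        pA = np.array([[0.01], [0.20]])
        pL = np.array([0.03, 0.50])
        assert ns.combine_snp_scores(pA, pL, "max")[0] == pytest.approx(0.03)

    def test_fisher_pair_example(self):
        # -2(ln 0.01 + ln 0.03) = 16.2235; chi2_4 survival ~ 2.73e-3
        pA = np.array([[0.01]])
        pL = np.array([0.03])
        score = ns.combine_snp_scores(pA, pL, "fisher")[0]
        x = -2 * (np.log(0.01) + np.log(0.03))
        assert x == pytest.approx(16.2235, abs=1e-4)
        assert score == pytest.approx(np.exp(-x / 2) * (1 + x / 2), rel=1e-12)
        assert score == pytest.approx(2.73e-3, rel=5e-3)

    def test_all_ones_boundary(self):
        pA = np.ones((2, 3))
        pL = np.ones(2)
        assert np.all(ns.combine_snp_scores(pA, pL, "max") == 1.0)
        assert np.all(ns.combine_snp_scores(pA, pL, "fisher") == 1.0)

    def test_zero_p_values_clamped_with_warning(self):
        pA = np.array([[0.0]])
        pL = np.array([0.5])
        with pytest.warns(UserWarning, match="clamped"):
            out = ns.combine_snp_scores(pA, pL, "max")
        assert 0 < out[0] <= 0.5

    def test_fisher_statistic_follows_chi_square_under_null(self, rng):
        pa, pl = rng.uniform(size=10_000), rng.uniform(size=10_000)
        statv = -2 * (np.log(pa) + np.log(pl))
        ks = stats.kstest(statv, stats.chi2(df=4).cdf).statistic
        assert ks < 0.02


class TestRetrievalAuc:
    def test_perfect_separation(self):
        assert ns.retrieval_auc([0.01, 0.02, 0.5, 0.9], [1, 1, 0, 0]) == 1.0

    def test_enumerated_pairs(self):
        assert ns.retrieval_auc([0.1, 0.2, 0.3, 0.4], [1, 0, 1, 0]) == 0.75

    def test_full_ties_give_half(self):
        assert ns.retrieval_auc([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0]) == 0.5

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=40)
        truth = rng.uniform(size=40) < 0.3
        truth[0], truth[1] = True, False
        a1 = ns.retrieval_auc(scores, truth)
        a2 = ns.retrieval_auc(np.log(scores / (1 + scores)), truth)
        assert a1 == pytest.approx(a2)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = np.round(rng.uniform(size=60), 1)  # force ties
        truth = rng.uniform(size=60) < 0.4
        truth[:2] = [True, False]
        assert ns.retrieval_auc(scores, truth) == pytest.approx(
            roc_auc_score(truth, -scores)
        )

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            ns.retrieval_auc([0.1, 0.2], [1, 1])


class TestBaselines:
    def test_single_snp_modes_coincide(self, rng):
        g = rng.binomial(2, 0.4, size=(200, 1))
        z = (g[:, 0] - g[:, 0].mean()) * 0.8 + rng.normal(size=200)
        y = rng.binomial(1, 1 / (1 + np.exp(-z)))
        uni = ns.baseline_snp_pvalues(g, y, "univariate")
        multi = ns.baseline_snp_pvalues(g, y, "multivariate")
        assert uni[0] == pytest.approx(multi[0], rel=1e-8)

    def test_null_snp_p_uniform(self, rng):
        pvals = []
        y = np.r_[np.zeros(60), np.ones(60)]
        for _ in range(600):
            g = rng.binomial(2, 0.3, size=(120, 1))
            pvals.append(ns.baseline_snp_pvalues(g, y, "univariate")[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_latent_phenotype_pvalue_length(self, rng):
        from neurosem.inference import LatentScores
        scores = LatentScores(values=rng.normal(size=(150, 3)),
                              group_ids=("a", "b", "c"))
        y = rng.binomial(1, 0.5, size=150)
        assert ns.latent_phenotype_pvalues(scores, y).shape == (3,)


class TestStudyDriver:
    def test_single_replicate_study_is_deterministic(self, small_config):
        r1 = ns.run_simulation_study(small_config, n_replicates=1, seed=5)
        r2 = ns.run_simulation_study(small_config, n_replicates=1, seed=5)
        assert r1.aic.equals(r2.aic)
        assert r1.auc.equals(r2.auc)
        assert list(r1.aic["model"]) == list(ns.AIC_MODELS)
        assert list(r1.auc["method"]) == list(ns.AUC_METHODS)

    def test_replicate_produces_five_aics_and_four_aucs(self, small_config):
        from neurosem.evaluate import evaluate_replicate
        aic, auc = evaluate_replicate(small_config, 12)
        assert set(aic) == set(ns.AIC_MODELS)
        assert set(auc) == set(ns.AUC_METHODS)
        assert all(np.isfinite(v) for v in aic.values())
        assert all(0 <= v <= 1 for v in auc.values())

    def test_sweep_tags_rows_with_parameter_value(self, small_config):
        res = ns.run_simulation_study(small_config, n_replicates=1, seed=5,
                                      sweep={"n_swaps": [0, 1]})
        assert set(res.auc["n_swaps"].unique()) == {0, 1}


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

p_values = st.floats(min_value=1e-12, max_value=1.0, allow_nan=False)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(2, 5), st.integers(2, 8), st.data())
def test_combined_scores_stay_probabilities_and_ignore_latent_order(m, p, data):
    pA = np.array(data.draw(st.lists(st.lists(p_values, min_size=p, max_size=p),
                                     min_size=m, max_size=m)))
    pL = np.array(data.draw(st.lists(p_values, min_size=m, max_size=m)))
    for method in ("max", "fisher"):
        s = ns.combine_snp_scores(pA, pL, method)
        assert np.all((s > 0) & (s <= 1))
        perm = np.random.default_rng(0).permutation(m)
        np.testing.assert_allclose(
            s, ns.combine_snp_scores(pA[perm], pL[perm], method))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=40),
       st.data())
def test_auc_complement_under_truth_flip(scores, data):
    n = len(scores)
    truth = np.array(data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n)))
    if truth.all() or not truth.any():
        truth[0], truth[1] = True, False
    a = ns.retrieval_auc(scores, truth)
    assert 0.0 <= a <= 1.0
    assert a + ns.retrieval_auc(scores, ~truth) == pytest.approx(1.0)
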