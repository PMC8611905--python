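import numpy as np
import pytest
from lifelines import CoxPHFitter
from scipy import optimize

from survclustae import SurvivalTable
from survclustae.survival import (cox_univariate, filter_bottleneck, km_curve,
                                  median_split_test, min_pairwise_logrank_p,
                                  pairwise_logrank)

from .oracles import naive_cox_loglik, naive_km_table


def _surv(time, event):
    time = np.asarray(time, float)
    return SurvivalTable([f"S{i}" for i in range(len(time))], time,
                         np.asarray(event, int))


class TestCoxUnivariate:
    def test_hand_dataset_matches_1d_likelihood_maximiser(self):
        time = [5.0, 8.0, 12.0, 20.0, 33.0]
        event = [1, 1, 0, 1, 1]
        x = [1.0, -0.5, 0.2, 0.8, -0.3]
        fit = cox_univariate(np.array(x), _surv(time, event))
        res = optimize.minimize_scalar(lambda b: -naive_cox_loglik(b, x, time, event),
                                       bounds=(-10, 10), method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.converged
        assert fit.beta == pytest.approx(res.x, abs=1e-4)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        time = rng.exponential(1000 * np.exp(-0.5 * x))
        event = (rng.random(n) < 0.8).astype(int)
        fit = cox_univariate(x, _surv(time, event))
        import pandas as pd
        cph = CoxPHFitter().fit(pd.DataFrame({"x": x, "T": time, "E": event}),
                                "T", "E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_binary_covariate_score_test_equals_logrank(self):
        rng = np.random.default_rng(1)
        n = 80
        group = rng.integers(0, 2, n)
        time = rng.exponential(np.where(group, 300, 900))
        event = np.ones(n, dtype=int)
        surv = _surv(time, event)
        fit = cox_univariate(group.astype(float), surv)
        p_lr = min_pairwise_logrank_p(surv, group)
        assert fit.p_value == pytest.approx(p_lr, rel=1e-6)

    def test_direction_agrees_with_km_ordering(self):
        # higher covariate -> shorter survival => positive beta, and the
        # high group's KM curve lies below the low group's
        rng = np.random.default_rng(2)
        for seed in range(20):
            r = np.random.default_rng(seed)
            group = r.integers(0, 2, 60)
            hr = r.uniform(2.0, 6.0)
            time = r.exponential(np.where(group, 500 / hr, 500))
            surv = _surv(time, np.ones(60, dtype=int))
            fit = cox_univariate(group.astype(float), surv)
            km_low = km_curve(surv, group == 0)
            km_high = km_curve(surv, group == 1)
            assert fit.beta > 0
            # median survival of the high-risk group is shorter
            med_low = km_low.times[np.searchsorted(-km_low.survival_prob, -0.5)]
            med_high = km_high.times[np.searchsorted(-km_high.survival_prob, -0.5)]
            assert med_high < med_low

    def test_zero_variance_flagged_not_crashed(self, small_survival):
        fit = cox_univariate(np.ones(10), small_survival)
        assert not fit.converged
        assert np.isnan(fit.hazard_ratio)
        assert fit.p_value == 1.0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_univariate(np.arange(4.0), _surv([1, 2, 3, 4], [0, 0, 0, 0]))

    def test_separation_capped_and_flagged(self):
        # perfectly ordered covariate: likelihood increases without bound
        time = np.arange(1.0, 9.0)
        x = -np.arange(8.0)
        fit = cox_univariate(x, _surv(time, np.ones(8, int)))
        assert np.isfinite(fit.beta)
        assert not fit.converged


class TestFilterBottleneck:
    def test_alpha_one_keeps_everything(self, small_survival):
        b = np.random.default_rng(0).normal(size=(10, 5))
        kept, table = filter_bottleneck(b, small_survival, alpha=1.0)
        assert len(kept) == 5
        assert set(table.columns) >= {"feature", "beta", "hazard_ratio", "p_value"}

    def test_risk_column_retained(self):
        rng = np.random.default_rng(3)
        n = 150
        risk = rng.normal(size=n)
        time = rng.exponential(1000 * np.exp(-risk))
        surv = _surv(time, np.ones(n, int))
        b = rng.normal(size=(n, 6))
        b[:, 2] = risk
        kept, _ = filter_bottleneck(b, surv, alpha=0.05)
        assert 2 in kept

    def test_zero_survivors_is_informative_error(self):
        rng = np.random.default_rng(4)
        surv = _surv(rng.exponential(100, 30), np.ones(30, int))
        b = rng.normal(size=(30, 3))
        with pytest.raises(ValueError, match="Cox filter"):
            filter_bottleneck(b, surv, alpha=1e-12)


class TestPairwiseLogrank:
    def test_planted_difference_detected(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 60)
        time = rng.exponential(np.where(labels, 100, 600))
        surv = _surv(time, np.ones(120, int))
        p = pairwise_logrank(surv, labels)
        assert p.loc[0, 1] < 1e-6
        assert p.loc[0, 1] == p.loc[1, 0]

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 60)
        time = rng.exponential(300, 60)
        surv = _surv(time, np.ones(60, int))
        p1 = pairwise_logrank(surv, labels).loc[0, 1]
        p2 = pairwise_logrank(surv, 1 - labels).loc[0, 1]
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_three_groups_matrix_shape(self):
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1, 2], 30)
        time = rng.exponential(300, 90)
        surv = _surv(time, np.ones(90, int))
        p = pairwise_logrank(surv, labels)
        assert p.shape == (3, 3)
        assert np.isnan(np.diag(p.to_numpy())).all()

    def test_single_group_rejected(self, small_survival):
        with pytest.raises(ValueError):
            pairwise_logrank(small_survival, np.zeros(10, int))

    def test_null_pvalues_roughly_uniform(self):
        # both groups share one survival distribution -> P ~ U(0,1)
        from scipy import stats
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 40)
            time = rng.exponential(500, 80)
            event = (rng.random(80) < 0.85).astype(int)
            ps.append(pairwise_logrank(_surv(time, event), labels).loc[0, 1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_curve(_surv([1.0, 2.0, 3.0], [1, 1, 1]))
        probs = dict(zip(km.times, km.survival_prob))
        assert probs[1.0] == pytest.approx(2 / 3)
        assert probs[2.0] == pytest.approx(1 / 3)
        assert probs[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = km_curve(_surv([5.0, 10.0], [0, 0]))
        np.testing.assert_allclose(km.survival_prob, 1.0)

    def test_mixed_censoring_matches_hand_table(self):
        time = [2.0, 3.0, 4.0, 5.0, 8.0, 9.0]
        event = [1, 0, 1, 1, 0, 1]
        km = km_curve(_surv(time, event))
        expected = dict(naive_km_table(time, event))
        got = dict(zip(km.times, km.survival_prob))
        for t, s in expected.items():
            assert got[t] == pytest.approx(s, abs=1e-12)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(8)
        time = rng.exponential(100, 25)
        km = km_curve(_surv(time, np.ones(25, int)))
        for t, s in zip(km.times, km.survival_prob):
            assert s == pytest.approx((time > t).mean(), abs=1e-12)


class TestMedianSplit:
    def test_even_split(self):
        rng = np.random.default_rng(9)
        surv = _surv(rng.exponential(100, 4), [1, 1, 1, 1])
        labels, p = median_split_test(np.array([1.0, 2.0, 3.0, 4.0]), surv)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])
        assert 0.0 <= p <= 1.0

    def test_all_equal_gives_na(self, small_survival):
        labels, p = median_split_test(np.full(10, 2.5), small_survival)
        assert labels is None
        assert np.isnan(p)

    def test_planted_prognostic_feature_significant(self, easy):
        dataset, truth = easy
        feature_id = "mrna:" + truth.informative_feature_ids["mrna"][0]
        col = dataset.feature_ids.index(feature_id)
        _, p = median_split_test(dataset.matrix[:, col], dataset.survival)
        assert p < 0.05
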