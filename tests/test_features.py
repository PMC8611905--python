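import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survclustae import MultiOmicsDataset, OmicsType, SurvivalTable
from survclustae.features import (AnovaTable, anova_per_feature, bonferroni_cut,
                                  consensus, novelty, top_features, twostep_scale,
                                  zscore_matrix)


def _dataset(blocks: dict[OmicsType, np.ndarray]):
    mats = list(blocks.values())
    n = mats[0].shape[0]
    matrix = np.hstack(mats)
    slices, ids, edge = {}, [], 0
    for omics, m in blocks.items():
        slices[omics] = slice(edge, edge + m.shape[1])
        ids.extend(f"{omics.value}:f{j}" for j in range(m.shape[1]))
        edge += m.shape[1]
    surv = SurvivalTable([f"S{i}" for i in range(n)], np.ones(n), np.ones(n, int))
    return MultiOmicsDataset(matrix, slices, [f"S{i}" for i in range(n)], ids, surv)


class TestTwostepScale:
    def test_median_norm_divides_by_feature_median(self):
        d = _dataset({OmicsType.MIRNA: np.array([[2.0], [4.0], [8.0]])})
        out = twostep_scale(d)
        # miRNA: after median norm [0.5, 1, 2], then row-wise unit norm -> 1s
        np.testing.assert_allclose(out.matrix.ravel(), [1.0, 1.0, 1.0])

    def test_robust_step_centers_and_scales(self):
        d = _dataset({OmicsType.MRNA: np.array([[1.0], [2.0], [3.0]])})
        out = twostep_scale(d)
        # median-norm: [0.5, 1, 1.5]; robust: median 1, IQR 0.5 -> [-1, 0, 1]
        np.testing.assert_allclose(out.matrix.ravel(), [-1.0, 0.0, 1.0])

    def test_mrna_block_medians_near_zero(self):
        rng = np.random.default_rng(0)
        d = _dataset({OmicsType.MRNA: rng.lognormal(1, 0.4, size=(30, 8)),
                      OmicsType.MIRNA: rng.lognormal(1, 0.4, size=(30, 4))})
        out = twostep_scale(d)
        med = np.median(out.block(OmicsType.MRNA), axis=0)
        np.testing.assert_allclose(med, 0.0, atol=1e-12)
        # miRNA rows are unit-norm instead
        np.testing.assert_allclose(
            np.linalg.norm(out.block(OmicsType.MIRNA), axis=1), 1.0, atol=1e-12)

    def test_per_sample_axis_option(self):
        d = _dataset({OmicsType.MRNA: np.array([[2.0, 4.0], [10.0, 20.0]])})
        out = twostep_scale(d, median_norm_axis="sample")
        assert "scaled" in out.log[-1]
        with pytest.raises(ValueError):
            twostep_scale(d, median_norm_axis="bogus")


class TestAnova:
    def test_constant_feature_gets_p_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        d = _dataset({OmicsType.MRNA: X})
        t = anova_per_feature(d, np.repeat([0, 1], 10))
        assert t.table.loc[1, "p_value"] == 1.0
        assert t.table.loc[1, "F"] == 0.0

    def test_label_like_feature_near_zero_p(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 2))
        X[:, 0] = labels + rng.normal(0, 0.01, 30)
        d = _dataset({OmicsType.MRNA: X})
        t = anova_per_feature(d, labels)
        assert t.table.loc[0, "p_value"] < 1e-20

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 12)
        X = rng.normal(size=(24, 5))
        d = _dataset({OmicsType.MRNA: X})
        t = anova_per_feature(d, labels)
        for j in range(5):
            tt = stats.ttest_ind(X[labels == 0, j], X[labels == 1, j])
            assert t.table.loc[j, "F"] == pytest.approx(tt.statistic ** 2, abs=1e-10)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1, 2], 8)
        X = rng.normal(size=(24, 4))
        d1 = _dataset({OmicsType.MRNA: X})
        d2 = _dataset({OmicsType.MRNA: X * [2.0, 0.5, 10.0, 1.0] + [1, -3, 0, 100]})
        t1 = anova_per_feature(d1, labels)
        t2 = anova_per_feature(d2, labels)
        np.testing.assert_allclose(t1.table["F"], t2.table["F"], atol=1e-8)

    def test_tiny_group_rejected(self):
        d = _dataset({OmicsType.MRNA: np.random.default_rng(5).normal(size=(5, 2))})
        with pytest.raises(ValueError):
            anova_per_feature(d, np.array([0, 0, 0, 0, 1]))


class TestTopFeatures:
    def _table(self, n, p_values, omics="mirna"):
        return AnovaTable(pd.DataFrame({
            "feature": [f"{omics}:f{j}" for j in range(n)],
            "omics_type": omics, "p_value": p_values,
            "rank": pd.Series(p_values).rank(method="first").astype(int)}))

    def test_pool_size_is_floor_of_ten_percent(self):
        t = self._table(420, np.linspace(1e-9, 1e-4, 420))
        out = top_features(t)
        assert len(out["mirna"]) == 42

    def test_insignificant_pool_is_empty(self):
        t = self._table(100, np.full(100, 0.5))
        assert top_features(t)["mirna"] == set()

    def test_bonferroni_threshold(self):
        assert bonferroni_cut(10) == pytest.approx(0.005)
        assert bonferroni_cut(20) == pytest.approx(0.0025)

    def test_planted_recall_with_truth_labels(self, easy):
        dataset, truth = easy
        scaled = twostep_scale(dataset)
        t = anova_per_feature(scaled, truth.cluster_labels)
        tops = top_features(t)
        for omics, planted in truth.informative_feature_ids.items():
            qualified = {f"{omics}:{f}" for f in planted}
            recall = len(tops[omics] & qualified) / len(qualified)
            fdp = len(tops[omics] - qualified) / max(1, len(tops[omics]))
            assert recall >= 0.9
            assert fdp <= 0.2


class TestConsensus:
    def test_counting_and_monotonicity(self):
        runs = [{"mrna": {"a", "b"}} for _ in range(10)]
        runs[0] = {"mrna": {"a"}}        # b missing here
        runs[1] = {"mrna": {"a", "c"}}   # and here; c appears 1/10
        rep = consensus(runs, n_runs=10)
        assert rep.counts["mrna"] == {"a": 10, "b": 8, "c": 1}
        assert rep.robust["mrna"] == {"a"}
        assert rep.at_least(6)["mrna"] >= rep.at_least(8)["mrna"] >= rep.robust["mrna"]

    def test_seven_of_ten_counts_at_six_only(self):
        runs = [{"mrna": {"x"}} if i < 7 else {"mrna": set()} for i in range(10)]
        rep = consensus(runs, n_runs=10)
        assert "x" in rep.at_least(6)["mrna"]
        assert "x" not in rep.at_least(8)["mrna"]

    def test_disjoint_runs_have_no_consensus(self):
        runs = [{"mrna": {f"f{i}"}} for i in range(10)]
        rep = consensus(runs, n_runs=10)
        assert rep.at_least(2)["mrna"] == set()

    def test_wrong_run_count_rejected(self):
        with pytest.raises(ValueError):
            consensus([{"mrna": set()}] * 3, n_runs=10)


class TestNovelty:
    def _rep(self, robust):
        return consensus([{"mrna": set(robust)}] * 10, n_runs=10)

    def test_set_difference(self):
        nov = novelty(self._rep({"a", "b", "c"}), [self._rep({"b"})])
        assert nov["mrna"] == {"a", "c"}

    def test_subset_gives_empty(self):
        nov = novelty(self._rep({"a"}), [self._rep({"a", "b"})])
        assert nov["mrna"] == set()

    def test_no_others_gives_robust(self):
        nov = novelty(self._rep({"a", "b"}), [])
        assert nov["mrna"] == {"a", "b"}


class TestZScoreMatrix:
    def test_clipping_and_constant_rows(self):
        X = np.random.default_rng(6).normal(size=(20, 3))
        X[:, 0] = 4.2                      # constant -> all-zero row
        X[0, 1] = X[:, 1].mean() + 50.0    # extreme -> clipped to 3
        d = _dataset({OmicsType.MRNA: X})
        labels = np.repeat([1, 0], 10)
        frame, order = zscore_matrix(d, ["mrna:f0", "mrna:f1"], labels)
        assert (frame.loc["mrna:f0"] == 0).all()
        assert frame.to_numpy().max() <= 3.0
        assert frame.to_numpy().min() >= -3.0
        # samples ordered by cluster label
        assert (np.diff(labels[order]) >= 0).all()

    def test_unknown_feature_rejected(self):
        d = _dataset({OmicsType.MRNA: np.ones((4, 2))})
        with pytest.raises(KeyError):
            zscore_matrix(d, ["mrna:nope"], np.zeros(4, int))
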