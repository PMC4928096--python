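import numpy as np
import pandas as pd
import pytest
from itertools import product

from pphrv import features as ft
from pphrv.rr_io import StimulusAnnotation


def _estimates_frame(t, columns, values=None):
    d = {"time": t}
    for i, c in enumerate(columns):
        d[c] = np.full(t.size, 1.0 + 0.1 * i) if values is None else values[c]
    return pd.DataFrame(d)


COLS = ("muRR", "sigmaRR", "sigmaHR", "LF", "HF", "LFHF", "LL", "LH", "HH",
        "AI", "SI", "lambda1", "lambda2")


def _ann(onset=60.0, offset=65.0, subject="s0", force=2.0, vel=9.4):
    return StimulusAnnotation(onset=onset, offset=offset, force_level=force,
                              velocity_level=vel, subject_id=subject,
                              rest_windows=((0.0, 40.0), (100.0, 140.0)))


class TestExtractStimulusFeatures:
    def test_constant_estimator_summaries(self):
        t = np.arange(0.0, 120.0, 0.1)
        frame = _estimates_frame(t, COLS)
        feats = ft.extract_stimulus_features(frame, [_ann()], COLS)
        f = feats[0]
        assert len(f.values) == 39
        for i in range(13):
            mx, med, mad = f.values[3 * i: 3 * i + 3]
            assert mx == pytest.approx(med)      # constant series
            assert mad == pytest.approx(0.0)
            assert med == pytest.approx(1.0)     # normalized by own baseline

    def test_39_dimensions_and_names(self):
        t = np.arange(0.0, 120.0, 0.1)
        feats = ft.extract_stimulus_features(_estimates_frame(t, COLS),
                                             [_ann()], COLS)
        names = feats[0].names
        assert len(names) == 13 * 3 == 39
        assert names[0] == "muRR__max" and names[-1] == "lambda2__mad"

    def test_short_stimulus_rejected(self):
        t = np.arange(0.0, 120.0, 0.1)
        ann = _ann(onset=60.0, offset=60.5)
        with pytest.raises(ValueError, match="lasts"):
            ft.extract_stimulus_features(_estimates_frame(t, COLS), [ann],
                                         COLS)

    def test_missing_rest_coverage_rejected(self):
        t = np.arange(50.0, 120.0, 0.1)  # starts after the rest window
        ann = StimulusAnnotation(onset=60.0, offset=65.0, force_level=2,
                                 velocity_level=9.4, subject_id="s0",
                                 rest_windows=((0.0, 55.0),))
        with pytest.raises(ValueError, match="rest"):
            ft.extract_stimulus_features(_estimates_frame(t, COLS), [ann],
                                         COLS)

    def test_non_finite_estimate_named(self):
        t = np.arange(0.0, 120.0, 0.1)
        frame = _estimates_frame(t, COLS)
        frame.loc[frame["time"].between(64.0, 64.5), "HF"] = np.nan
        with pytest.raises(ValueError, match="HF"):
            ft.extract_stimulus_features(frame, [_ann()], COLS)


class TestRemoveOutliers:
    def _table(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"a": rng.standard_normal(n),
                             "b": rng.standard_normal(n)})

    def test_no_outliers_identity(self):
        t = self._table()
        out, removed = ft.remove_outliers(t)
        assert removed == []
        pd.testing.assert_frame_equal(out, t)

    def test_planted_outlier_removed(self):
        t = self._table(n=30)
        t.loc[7, "a"] = 50.0  # far beyond 4 SD
        out, removed = ft.remove_outliers(t)
        assert removed == [7]
        # direct z recomputation
        x = t["a"].to_numpy()
        z = (x - x.mean()) / x.std(ddof=1)
        assert abs(z[7]) > 4

    def test_zero_variance_dimension_skipped(self):
        t = self._table()
        t["c"] = 1.0
        out, removed = ft.remove_outliers(t)
        assert removed == []

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="3 rows"):
            ft.remove_outliers(self._table(n=2))


class TestWilcoxonScreen:
    def test_identical_samples_give_p_one(self):
        a = pd.DataFrame({"f": np.arange(10.0)})
        p = ft.wilcoxon_screen(a, a.copy())
        assert p["f"] == 1.0

    def test_exact_case_matches_enumeration(self):
        # n=5: enumerate all 2^5 sign assignments of the rank sum
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.4, 2.5, 1.0, 3.0, 4.1])
        d = x - y
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        w_obs = ranks[d > 0].sum()
        n = len(d)
        stats = []
        for signs in product([0, 1], repeat=n):
            stats.append(sum(r for r, s in zip(ranks, signs) if s))
        stats = np.array(stats)
        w_min = min(w_obs, ranks.sum() - w_obs)
        p_exact = np.mean(np.minimum(stats, ranks.sum() - stats) <= w_min)
        p = ft.wilcoxon_screen(pd.DataFrame({"f": x}), pd.DataFrame({"f": y}))
        assert p["f"] == pytest.approx(p_exact, abs=1e-12)

    def test_power_on_planted_shift(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.standard_normal(32)
            shifted = base + 1.0 + 0.2 * rng.standard_normal(32)
            p = ft.wilcoxon_screen(pd.DataFrame({"f": shifted}),
                                   pd.DataFrame({"f": base}))
            hits += p["f"] < 0.05
        assert hits >= 90

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ft.wilcoxon_screen(pd.DataFrame({"f": [1.0, 2.0]}),
                               pd.DataFrame({"f": [1.0]}))


class TestLooClassify:
    def _separable(self, n=64, p=39, sep=10.0, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X[y == "b", :5] += sep
        return X, y

    def test_separable_data_high_accuracy(self):
        X, y = self._separable()
        res = ft.loo_classify(X, y)
        assert res.accuracy >= 95.0

    def test_confusion_rows_sum_to_100(self):
        X, y = self._separable(n=20, sep=1.0)
        res = ft.loo_classify(X, y)
        np.testing.assert_allclose(res.confusion.sum(axis=1), 100.0,
                                   atol=1e-9)

    def test_permuted_labels_chance_level(self):
        X, y = self._separable()
        accs = []
        for s in range(20):
            yp = np.random.default_rng(100 + s).permutation(y)
            accs.append(ft.loo_classify(X, yp).accuracy)
        assert 35.0 <= np.mean(accs) <= 65.0

    def test_determinism(self):
        X, y = self._separable(n=24, sep=2.0)
        r1 = ft.loo_classify(X, y)
        r2 = ft.loo_classify(X, y)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)

    def test_no_test_set_leakage(self):
        # every fold's prediction must be reproducible from normalization
        # constants computed on the training split alone
        from sklearn.svm import NuSVC

        from pphrv.features import _median_mad_scale, _scale_apply
        X, y = self._separable(n=20, sep=2.0)
        res = ft.loo_classify(X, y)
        n, p = X.shape
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            med, mad = _median_mad_scale(X[mask])
            clf = NuSVC(nu=0.5, kernel="rbf", gamma=1.0 / p)
            clf.fit(_scale_apply(X[mask], med, mad), y[mask])
            pred = clf.predict(_scale_apply(X[i], med, mad)[None, :])[0]
            assert pred == res.predictions[i]

    def test_underpopulated_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            ft.loo_classify(X, y)


class TestSvmRfeRank:
    def test_planted_informative_dims_ranked_top(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((64, 39))
        y = np.array(["a"] * 32 + ["b"] * 32)
        X[y == "b", :3] += 10.0
        ranks, curve = ft.svm_rfe_rank(X, y)
        assert np.all(np.sort(ranks[:3]) <= np.sort(ranks)[4])  # in top 5
        assert curve.size == 39

    def test_ranks_are_permutation_per_fold(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 6))
        y = np.array(["a"] * 6 + ["b"] * 6)
        X[y == "b", 0] += 3.0
        from pphrv.features import _median_mad_scale, _rfe_fold_ranks, _scale_apply
        med, mad = _median_mad_scale(X)
        r = _rfe_fold_ranks(_scale_apply(X, med, mad), y, 0.5, 1 / 6.0, 0.95)
        assert sorted(r) == list(range(1, 7))

    def test_single_feature_degenerate(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((16, 1))
        y = np.array(["a"] * 8 + ["b"] * 8)
        X[y == "b", 0] += 4.0
        ranks, curve = ft.svm_rfe_rank(X, y)
        np.testing.assert_array_equal(ranks, [1.0])
        assert curve.size == 1
        assert curve[0] == ft.loo_classify(X, y).accuracy
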