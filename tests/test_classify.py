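import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braingmm.classify import (
    LabeledDataset,
    compute_metrics,
    evaluate,
    fit_predict_nb,
    fit_predict_pnn,
    fit_predict_svm,
    loocv,
    roc_auc,
)


def _two_clouds(rng, n=20, sep=10.0, d=2):
    a = rng.normal(0.0, 1.0, (n, d))
    b = rng.normal(sep, 1.0, (n, d))
    X = np.vstack([a, b])
    y = np.array(["GBM"] * n + ["normal"] * n)
    return X, y


class TestKernelNB:
    def test_training_point_far_classes(self, rng):
        X, y = _two_clouds(rng, sep=20.0)
        pred, post = fit_predict_nb(LabeledDataset(X, y), X[:1])
        assert pred[0] == "GBM" and post[0] > 0.99

    def test_midpoint_symmetry(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["GBM", "GBM", "normal", "normal"])
        _, post = fit_predict_nb(LabeledDataset(X, y), np.array([[0.0]]))
        assert post[0] == pytest.approx(0.5, abs=1e-6)

    def test_matches_hand_kde_oracle(self):
        """1-D scores equal a direct Silverman kernel-density summation."""
        xa = np.array([0.0, 1.0, 2.0, 3.0])
        xb = np.array([7.0, 8.0, 9.0, 11.0])
        X = np.concatenate([xa, xb])[:, None]
        y = np.array(["GBM"] * 4 + ["normal"] * 4)
        test = np.array([[2.5], [8.5]])

        def kde(x0, pts):
            n = pts.size
            sd = pts.std(ddof=1)
            iqr = np.percentile(pts, 75) - np.percentile(pts, 25)
            h = 0.9 * min(sd, iqr / 1.34) * n ** (-0.2)
            z = (x0 - pts) / h
            return np.mean(np.exp(-0.5 * z**2) / (h * np.sqrt(2 * np.pi)))

        _, post = fit_predict_nb(LabeledDataset(X, y), test)
        for i, x0 in enumerate([2.5, 8.5]):
            pa, pb = 0.5 * kde(x0, xa), 0.5 * kde(x0, xb)
            assert post[i] == pytest.approx(pa / (pa + pb), rel=1e-9)

    def test_single_class_training_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            fit_predict_nb(LabeledDataset(X, np.array(["GBM"] * 4)), X)


class TestSVM:
    def test_separable_clouds_perfect(self, rng):
        X, y = _two_clouds(rng, sep=15.0)
        Xt, yt = _two_clouds(np.random.default_rng(7), sep=15.0)
        pred, _ = fit_predict_svm(LabeledDataset(X, y), Xt)
        assert np.all(pred == yt)

    def test_label_swap_negates_decision(self, rng):
        X, y = _two_clouds(rng, sep=5.0, n=10)
        test = rng.normal(2.5, 1.0, (6, 2))
        _, dec = fit_predict_svm(LabeledDataset(X, y), test)
        swapped = np.where(y == "GBM", "normal", "GBM")
        _, dec_swapped = fit_predict_svm(LabeledDataset(X, swapped), test)
        assert np.allclose(dec, -dec_swapped, atol=1e-3)

    def test_duplicate_training_point_correct(self, rng):
        X, y = _two_clouds(rng, sep=12.0)
        pred, _ = fit_predict_svm(LabeledDataset(X, y), X[[0, -1]])
        assert pred.tolist() == ["GBM", "normal"]


class TestPNN:
    def test_training_point_small_spread(self, rng):
        X, y = _two_clouds(rng, sep=8.0)
        pred, post = fit_predict_pnn(LabeledDataset(X, y), X[:1], spread=0.05)
        assert pred[0] == "GBM" and post[0] > 0.99

    def test_equidistant_between_single_point_classes(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array(["GBM", "normal"])
        _, post = fit_predict_pnn(LabeledDataset(X, y), np.array([[1.0, 0.0]]), spread=0.5)
        assert post[0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_kernel_sum_oracle(self, rng):
        X, y = _two_clouds(rng, sep=3.0, n=5)
        test = rng.normal(1.5, 1.0, (4, 2))
        spread = 0.7
        _, post = fit_predict_pnn(LabeledDataset(X, y), test, spread=spread)
        for i in range(4):
            dens = {}
            for c in ("GBM", "normal"):
                pts = X[y == c]
                d2 = ((test[i] - pts) ** 2).sum(axis=1)
                dens[c] = np.mean(np.exp(-d2 / (2 * spread**2)))
            expected = dens["GBM"] / (dens["GBM"] + dens["normal"])
            assert post[i] == pytest.approx(expected, rel=1e-9)


class TestLOOCV:
    def test_fold_count_contract(self, rng):
        X, y = _two_clouds(rng, n=17)
        preds, scores = loocv(LabeledDataset(X, y), "nb")
        assert preds.shape == (34,) and scores.shape == (34,)

    def test_deterministic_repeat(self, rng):
        X, y = _two_clouds(rng, n=8)
        data = LabeledDataset(X, y)
        p1, s1 = loocv(data, "pnn")
        p2, s2 = loocv(data, "pnn")
        assert np.array_equal(p1, p2) and np.array_equal(s1, s2)

    def test_memorizing_probe_on_duplicated_points(self, rng):
        """A 1-NN probe scores 100% when every point has an identical twin."""

        def one_nn(train, test_X, pos_label="GBM", **kw):
            d = ((test_X[:, None, :] - train.features[None, :, :]) ** 2).sum(axis=2)
            idx = np.argmin(d, axis=1)
            pred = train.labels[idx]
            return pred, (pred == pos_label).astype(float)

        Xh, yh = _two_clouds(rng, n=6, sep=4.0)
        X = np.vstack([Xh, Xh])
        y = np.concatenate([yh, yh])
        preds, _ = loocv(LabeledDataset(X, y), one_nn, standardize=False)
        assert np.all(preds == y)

    def test_single_class_fold_named(self):
        X = np.arange(6.0).reshape(3, 2)
        y = np.array(["GBM", "GBM", "normal"])
        with pytest.raises(ValueError, match="2"):
            loocv(LabeledDataset(X, y), "nb")

    def test_grouped_mode_holds_out_whole_patient(self, rng):
        X, y = _two_clouds(rng, n=6, sep=10.0)
        groups = np.array([i // 2 for i in range(6)] + [i // 2 for i in range(6)])
        preds, _ = loocv(LabeledDataset(X, y, groups=groups), "nb", group_by_patient=True)
        assert preds.shape == (12,)

    def test_pca_transform_inside_folds(self, rng):
        X, y = _two_clouds(rng, n=10, d=5, sep=8.0)
        preds, _ = loocv(LabeledDataset(X, y), "nb", pca_components=3)
        assert (preds == y).mean() >= 0.95


class TestMetrics:
    def test_all_correct(self):
        y = np.array(["GBM"] * 17 + ["normal"] * 17)
        m = compute_metrics(y, y)
        assert (m["accuracy"], m["false_alarm"], m["missed_detection"]) == (100.0, 0.0, 0.0)

    def test_one_missed_gbm_of_34(self):
        y = np.array(["GBM"] * 17 + ["normal"] * 17)
        pred = y.copy()
        pred[0] = "normal"
        m = compute_metrics(pred, y)
        assert m["missed_detection"] == pytest.approx(100.0 / 34)
        assert m["accuracy"] == pytest.approx(100.0 * 33 / 34)
        assert m["false_alarm"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 60))
    def test_identity_and_counting_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        y = rng.choice(["GBM", "normal"], n)
        pred = rng.choice(["GBM", "normal"], n)
        m = compute_metrics(pred, y)
        assert m["accuracy"] + m["false_alarm"] + m["missed_detection"] == pytest.approx(
            100.0, abs=1e-9
        )
        missed = sum(1 for p, t in zip(pred, y) if t == "GBM" and p != t)
        assert m["missed_detection"] == pytest.approx(100.0 * missed / n)


class TestROC:
    def test_perfect_separation(self):
        y = np.array(["GBM"] * 5 + ["normal"] * 5)
        s = np.array([0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.3, 0.05, 0.15])
        *_, auc = roc_auc(s, y)
        assert auc == 100.0

    def test_label_inversion_complements_auc(self, rng):
        y = rng.choice(["GBM", "normal"], 20)
        while len(set(y)) < 2:
            y = rng.choice(["GBM", "normal"], 20)
        s = rng.normal(size=20)
        *_, auc = roc_auc(s, y)
        inverted = np.where(y == "GBM", "normal", "GBM")
        *_, auc_inv = roc_auc(s, inverted)
        assert auc_inv == pytest.approx(100.0 - auc)

    def test_ties_match_mann_whitney_oracle(self):
        s = np.array([0.5, 0.5, 0.7, 0.2, 0.9, 0.5])
        y = np.array(["GBM", "normal", "GBM", "normal", "GBM", "GBM"])
        *_, auc = roc_auc(s, y)
        pos = s[y == "GBM"]
        neg = s[y != "GBM"]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        assert auc == pytest.approx(100.0 * np.mean(pairs))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array(["GBM", "GBM"]))


class TestEvaluate:
    def test_report_covers_all_classifiers(self, rng):
        X, y = _two_clouds(rng, n=10)
        report = evaluate(LabeledDataset(X, y))
        assert set(report.results) == {"nb", "svm", "pnn"}
        df = report.to_dataframe()
        assert np.allclose(
            df["accuracy"] + df["false_alarm"] + df["missed_detection"], 100.0
        )
        assert df["auc"].between(0, 100).all()

    def test_shuffled_labels_near_chance(self, rng):
        X, _ = _two_clouds(rng, n=40, sep=12.0)
        y = rng.permutation(np.array(["GBM"] * 40 + ["normal"] * 40))
        report = evaluate(LabeledDataset(X, y), classifiers=("nb",))
        assert 35.0 <= report.results["nb"]["accuracy"] <= 65.0
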