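import numpy as np
import pandas as pd
import pytest

from aquaspec import (SpectraSet, assign_classes, classification_metrics,
                      classify, cross_validate, extract_band_vectors, fit_pls2,
                      one_hot, predict, rmse_profile,
                      split_calibration_prediction, venetian_blinds)
from aquaspec.plsda import CvResult
from aquaspec.preprocess import MODEL_PPT


class TestEncodingAndFolds:
    def test_one_hot_rows_and_order(self):
        Y, classes = one_hot(["b", "a", "b"])
        assert classes == ["a", "b"]
        np.testing.assert_array_equal(Y, [[0, 1], [1, 0], [0, 1]])
        np.testing.assert_array_equal(Y.sum(axis=0), [1, 2])
        assert [classes[i] for i in Y.argmax(axis=1)] == ["b", "a", "b"]

    def test_one_hot_single_class_rejected(self):
        with pytest.raises(ValueError):
            one_hot(["a", "a"])

    def test_venetian_blinds_interleaves(self):
        np.testing.assert_array_equal(venetian_blinds(10, 10), np.arange(10))
        folds = venetian_blinds(12, 10)
        counts = np.bincount(folds, minlength=10)
        assert counts[0] == counts[1] == 2 and set(counts) <= {1, 2}
        assert counts.max() - counts.min() <= 1

    def test_venetian_blinds_order_dependent(self):
        # documented behaviour: folds follow dataset order, so reordering
        # the samples changes the assignment
        folds = venetian_blinds(6, 3)
        perm = np.array([5, 0, 1, 2, 3, 4])
        assert not np.array_equal(folds[perm], venetian_blinds(6, 3))

    def test_venetian_blinds_bad_args(self):
        with pytest.raises(ValueError):
            venetian_blinds(5, 10)


class TestSplit:
    def _design(self):
        counts = {"621-17": 21, "Erez": 30, "505": 25, "240": 25,
                  "Gen12": 30, "156": 26, "45-3": 30}
        rows = [{"sample_id": f"{g}-{i}", "chemovar": g}
                for g, n in counts.items() for i in range(n)]
        wl = np.array([1300.0, 1302.0])
        return SpectraSet(wl, np.zeros((len(rows), 2)), pd.DataFrame(rows))

    def test_study_design_yields_125_62(self):
        cal, pred = split_calibration_prediction(self._design(), 0.67, seed=0)
        assert len(cal) == 125 and len(pred) == 62
        assert len(set(cal) | set(pred)) == 187

    def test_half_split_balanced(self):
        rows = [{"sample_id": f"{g}{i}", "chemovar": g}
                for g in "ab" for i in range(4)]
        s = SpectraSet(np.array([1300.0, 1302.0]), np.zeros((8, 2)),
                       pd.DataFrame(rows))
        cal, pred = split_calibration_prediction(s, 0.5, seed=3)
        assert len(cal) == 4 and len(pred) == 4

    def test_seed_determinism(self):
        s = self._design()
        a1, _ = split_calibration_prediction(s, 0.67, seed=5)
        a2, _ = split_calibration_prediction(s, 0.67, seed=5)
        b, _ = split_calibration_prediction(s, 0.67, seed=6)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, b)


class TestSimpls:
    def test_collinear_single_component_exact(self, rng):
        # with mutually orthogonal (centred) predictors, one latent variable
        # recovers a response collinear with a single column exactly
        raw = rng.standard_normal((20, 5))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = 2.0 * X[:, [2]] + 1.0
        m = fit_pls2(X, y, 1)
        np.testing.assert_allclose(predict(m, X), y, atol=1e-10)

    def test_max_lv_equals_least_squares(self, rng):
        X = rng.standard_normal((6, 4))
        Y, _ = one_hot(["a", "a", "b", "b", "c", "c"])
        m = fit_pls2(X, Y, 4)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        B_ls = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        np.testing.assert_allclose(predict(m, X), Xc @ B_ls + Y.mean(axis=0),
                                   atol=1e-8)

    def test_duplicating_samples_keeps_regression_matrix(self, rng):
        X = rng.standard_normal((15, 8))
        Y, _ = one_hot(list("aabbc") * 3)
        m1 = fit_pls2(X, Y, 3)
        m2 = fit_pls2(np.vstack([X, X]), np.vstack([Y, Y]), 3)
        np.testing.assert_allclose(m1.regression_matrix, m2.regression_matrix,
                                   atol=1e-8)

    def test_predict_is_affine(self, rng):
        X = rng.standard_normal((20, 6))
        Y, _ = one_hot(list("ab") * 10)
        m = fit_pls2(X, Y, 3)
        x1, x2 = rng.standard_normal((2, 6))
        a = 0.3
        np.testing.assert_allclose(
            predict(m, (a * x1 + (1 - a) * x2)[None, :]),
            a * predict(m, x1[None, :]) + (1 - a) * predict(m, x2[None, :]),
            atol=1e-10)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.standard_normal((20, 6))
        Y, _ = one_hot(list("ab") * 10)
        m = fit_pls2(X, Y, 3)
        np.testing.assert_allclose(predict(m, m.x_mean[None, :]),
                                   m.y_mean[None, :], atol=1e-10)

    def test_explained_variance_bounded(self, rng):
        X = rng.standard_normal((30, 10))
        Y, _ = one_hot(list("abc") * 10)
        m = fit_pls2(X, Y, 5)
        assert np.all(m.explained_x_variance >= 0)
        assert m.explained_x_variance.sum() <= 100 + 1e-8
        assert m.explained_y_variance.sum() <= 100 + 1e-8

    def test_matches_sklearn_on_single_response(self, rng):
        # independent cross-check: SIMPLS and NIPALS coincide for one y column
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((30, 12))
        y = X @ rng.standard_normal(12) + 0.1 * rng.standard_normal(30)
        m = fit_pls2(X, y[:, None], 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(predict(m, X).ravel(),
                                   ref.predict(X).ravel(), atol=1e-8)

    def test_rank_deficient_truncates_with_warning(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])  # rank 1
        Y, _ = one_hot(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="latent variables"):
            m = fit_pls2(X, Y, 2)
        assert m.effective_n_lv == 1


class TestAssignAndVectors:
    def test_argmax_assignment(self):
        scores = np.array([[0.9, 0.2, 0.1]])
        assert assign_classes(scores, ["A", "B", "C"])[0] == "A"

    def test_tie_goes_to_first_sorted_class(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="aquaspec.plsda"):
            out = assign_classes(np.array([[0.5, 0.5]]), ["A", "B"])
        assert out[0] == "A"
        assert any("tied" in r.message for r in caplog.records)

    def test_all_equal_batch(self):
        out = assign_classes(np.zeros((4, 3)), ["A", "B", "C"])
        assert list(out) == ["A"] * 4

    def test_band_vector_count_and_identity(self, rng):
        X = rng.standard_normal((20, 6))
        Y, classes = one_hot(list("ab") * 10)
        m = fit_pls2(X, Y, 3, class_labels=classes)
        vecs = extract_band_vectors(m, np.arange(6))
        assert list(vecs.columns) == ["LV1", "LV2", "LV3", "regvec:a", "regvec:b"]
        assert len(vecs) == 6
        # regression vectors reproduce predict() applied manually
        manual = (X - m.x_mean) @ vecs[["regvec:a", "regvec:b"]].to_numpy() + m.y_mean
        np.testing.assert_allclose(manual, predict(m, X), atol=1e-10)


def _two_class_set(rng, n=40, sep=1.0):
    wl = np.arange(1300, 1341, 2.0)
    lab = np.array(["a", "b"] * (n // 2))
    shift = np.where(lab == "a", sep, -sep)[:, None]
    X = 0.5 + shift * np.exp(-0.5 * ((wl - 1320) / 8) ** 2) \
        + 0.01 * rng.standard_normal((n, wl.size))
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                         "chemovar": lab, "major_class": lab})
    return SpectraSet(wl, X, meta)


class TestCrossValidation:
    def test_separable_classes_no_cv_errors(self, rng):
        s = _two_class_set(rng)
        _, cv = cross_validate(s, "major_class", 2, k=10)
        assert (cv.oof_labels == cv.true_labels).all()

    def test_loo_equals_manual_loop(self, rng):
        s = _two_class_set(rng, n=12)
        _, cv = cross_validate(s, "major_class", 2, k=12)
        labels = s.groups("major_class").to_numpy()
        Y, classes = one_hot(labels)
        manual = np.zeros_like(cv.oof_scores)
        for i in range(12):
            mask = np.arange(12) != i
            m = fit_pls2(s.absorbance[mask], Y[mask], 2, class_labels=classes)
            manual[i] = predict(m, s.absorbance[[i]])
        np.testing.assert_allclose(cv.oof_scores, manual, atol=1e-10)

    def test_shuffled_labels_near_chance(self, rng):
        s = _two_class_set(rng, n=60)
        labels = rng.permutation(s.samples["major_class"].to_numpy())
        s.samples["major_class"] = labels
        _, cv = cross_validate(s, "major_class", 2, k=10)
        acc = np.mean(cv.oof_labels == cv.true_labels)
        assert acc < 0.75  # majority rate 0.5 plus binomial slack for n=60

    def test_confusion_count_identities(self, rng):
        s = _two_class_set(rng)
        _, cv = cross_validate(s, "major_class", 2, k=10)
        conf = cv.confusion("cross_validation")
        for cls, row in conf.iterrows():
            assert row.TP + row.FN == (cv.true_labels == cls).sum()
            assert row.TP + row.FP + row.TN + row.FN == len(cv.true_labels)


class TestMetricsAndRmse:
    def _cv_from_labels(self, true, pred):
        classes = sorted(set(true))
        Y = (np.asarray(true)[:, None] == np.asarray(classes)[None, :]).astype(float)
        return CvResult(folds=np.zeros(len(true), int), class_labels=classes,
                        oof_scores=Y, oof_labels=np.asarray(pred),
                        cal_scores=Y, cal_labels=np.asarray(pred),
                        true_labels=np.asarray(true))

    def test_sensitivity_arithmetic(self):
        cv = self._cv_from_labels(["a"] * 4 + ["b"] * 4,
                                  ["a", "a", "a", "b", "b", "b", "b", "b"])
        met = classification_metrics(cv)
        sens_a = met[(met["class"] == "a")
                     & (met.tier == "cross_validation")].sensitivity.item()
        assert sens_a == pytest.approx(0.750)

    def test_perfect_tier_all_ones(self, rng):
        s = _two_class_set(rng)
        _, cv = cross_validate(s, "major_class", 2, k=10)
        met = classification_metrics(cv)
        assert (met[["sensitivity", "specificity", "accuracy"]] == 1).all().all()

    def test_metrics_equal_bruteforce_recount(self, rng):
        true = rng.choice(list("abc"), 60)
        pred = rng.choice(list("abc"), 60)
        met = classification_metrics(self._cv_from_labels(true, pred))
        for _, row in met[met.tier == "cross_validation"].iterrows():
            c = row["class"]
            tp = np.sum((true == c) & (pred == c))
            fn = np.sum((true == c) & (pred != c))
            tn = np.sum((true != c) & (pred != c))
            fp = np.sum((true != c) & (pred == c))
            assert row.sensitivity == pytest.approx(tp / (tp + fn))
            assert row.specificity == pytest.approx(tn / (tn + fp))
            assert row.accuracy == pytest.approx((tp + tn) / 60)
            # sensitivity * class size recovers an integer count
            assert round(row.sensitivity * (tp + fn), 6) == pytest.approx(tp)

    def test_rmse_arithmetic(self):
        true = np.array(["a", "a", "b", "b"])
        Y = (true[:, None] == np.array(["a", "b"])[None, :]).astype(float)
        scores = Y.copy()
        scores[0, 0] += 0.1
        scores[1, 0] -= 0.1
        cv = CvResult(folds=np.zeros(4, int), class_labels=["a", "b"],
                      oof_scores=scores, oof_labels=true, cal_scores=Y,
                      cal_labels=true, true_labels=true)
        prof = rmse_profile(cv)
        assert prof.loc["a", "RMSECV"] == pytest.approx(0.1 / np.sqrt(2))
        assert prof.loc["a", "RMSEC"] == 0
        assert prof.loc["b", "RMSECV"] == 0

    def test_exact_fit_zero_rmse(self, rng):
        s = _two_class_set(rng, sep=2.0)
        _, cv = cross_validate(s, "major_class", 2, k=10)
        prof = rmse_profile(cv)
        assert (prof["RMSEC"] >= 0).all() and (prof["RMSECV/RMSEC"] > 0).all()


def test_high_separation_cv_sensitivity(default_spectra):
    """Between-class band separation >= 5x within-class noise in the default
    design gives per-class CV sensitivity >= 0.95."""
    run = classify(default_spectra, "major_class", 8, k=10, frac=0.67,
                   seed=0, steps=MODEL_PPT)
    met = run.metrics
    cv_sens = met[met.tier == "cross_validation"].sensitivity
    assert (cv_sens >= 0.95).all()
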