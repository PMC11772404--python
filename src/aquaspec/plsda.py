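"""PLS2 discriminant analysis with venetian-blinds cross-validation.

The classifier is partial least squares regression of the spectra onto a
class-indicator matrix (PLS-DA), fitted with the deterministic SIMPLS
deflation (de Jong 1993).  Model quality is reported the way the NIR
chemometrics literature does: per-class sensitivity / specificity /
accuracy for the calibration, cross-validation and independent-prediction
tiers, plus RMSEC / RMSECV / RMSEP and their over-fitting ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Pipeline, PptStep
from .spectra import SpectraSet

logger = logging.getLogger(__name__)

TIERS = ("calibration", "cross_validation", "prediction")


# -- encoding and folds ----------------------------------------------------

def one_hot(labels) -> tuple[np.ndarray, list]:
    """Class-indicator matrix with columns in sorted label order."""
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("one_hot requires at least 2 classes")
    Y = (labels[:, None] == np.asarray(classes)[None, :]).astype(float)
    return Y, classes


def venetian_blinds(n: int, k: int) -> np.ndarray:
    """Fold index per sample: sample i (dataset order) goes to fold i mod k.

    Deterministic and order-dependent by construction — reordering the
    samples changes the folds.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"n={n} smaller than k={k} folds")
    return np.arange(n) % k


def split_calibration_prediction(s: SpectraSet, frac: float = 0.67,
                                 seed: int = 0, by: str = "chemovar"
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split into calibration and prediction row indices.

    Per stratum, round(frac * n) samples go to calibration, the rest to
    prediction.  With the study design of 187 samples over chemovar counts
    {21, 30, 25, 25, 30, 26, 30} and frac 0.67 this yields 125 / 62.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    labels = s.groups(by)
    rng = np.random.default_rng(seed)
    cal, pred = [], []
    for name in sorted(pd.unique(labels).tolist()):
        idx = np.flatnonzero((labels == name).to_numpy())
        if idx.size < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 samples")
        n_cal = int(np.floor(frac * idx.size + 0.5))
        perm = rng.permutation(idx)
        cal.append(np.sort(perm[:n_cal]))
        pred.append(np.sort(perm[n_cal:]))
    return np.concatenate(cal), np.concatenate(pred)


# -- SIMPLS ----------------------------------------------------------------

@dataclass
class PlsModel:
    """Fitted PLS2-DA state."""

    n_lv: int                      # requested latent variables
    effective_n_lv: int            # after any rank-deficiency truncation
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray            # R, (p, n_lv): X weights, scores T = Xc @ R
    x_loadings: np.ndarray         # P, (p, n_lv)
    y_loadings: np.ndarray         # Q, (n_classes, n_lv)
    x_scores: np.ndarray           # T, (n, n_lv), orthonormal columns
    regression_matrix: np.ndarray  # B, (p, n_classes)
    class_labels: list
    explained_x_variance: np.ndarray  # % of X sum of squares per LV
    explained_y_variance: np.ndarray  # % of Y sum of squares per LV


def fit_pls2(X: np.ndarray, Y: np.ndarray, n_lv: int,
             class_labels: list | None = None, rank_tol: float = 1e-12) -> PlsModel:
    """Fit PLS2 by SIMPLS: deterministic, no random initialisation.

    X and Y are centred internally.  If a deflation step becomes rank
    deficient the number of latent variables is reduced with a warning and
    the effective count recorded.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, p = X.shape
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} exceeds min(n-1, p)={min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = X - x_mean
    Y0 = Y - y_mean
    ssx = np.sum(X0 * X0)
    ssy = np.sum(Y0 * Y0)

    S = X0.T @ Y0
    R = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    V = np.zeros((p, n_lv))  # orthonormal basis for deflation
    eff = n_lv
    for a in range(n_lv):
        u, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] < rank_tol:
            eff = a
            warnings.warn(f"rank-deficient SIMPLS step at LV {a + 1}; "
                          f"using {eff} latent variables")
            break
        r = u[:, 0]
        t = X0 @ r
        normt = np.linalg.norm(t)
        if normt < rank_tol:
            eff = a
            warnings.warn(f"degenerate score at LV {a + 1}; using {eff} latent variables")
            break
        t /= normt
        r /= normt
        pvec = X0.T @ t
        q = Y0.T @ t
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        v /= np.linalg.norm(v)
        S -= v[:, None] * (v @ S)[None, :]
        R[:, a], P[:, a], Q[:, a], T[:, a], V[:, a] = r, pvec, q, t, v

    R, P, Q, T = R[:, :eff], P[:, :eff], Q[:, :eff], T[:, :eff]
    B = R @ Q.T
    with np.errstate(invalid="ignore", divide="ignore"):
        expl_x = 100.0 * np.sum(P * P, axis=0) / ssx if ssx > 0 else np.zeros(eff)
        expl_y = 100.0 * np.sum(Q * Q, axis=0) / ssy if ssy > 0 else np.zeros(eff)
    return PlsModel(n_lv=n_lv, effective_n_lv=eff, x_mean=x_mean, y_mean=y_mean,
                    weights=R, x_loadings=P, y_loadings=Q, x_scores=T,
                    regression_matrix=B,
                    class_labels=list(class_labels) if class_labels is not None else [],
                    explained_x_variance=expl_x, explained_y_variance=expl_y)


def predict(m: PlsModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted class scores: (X_new - x_mean) @ B + y_mean."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != m.x_mean.size:
        raise ValueError(f"X_new has {X_new.shape[1]} wavelengths, model expects "
                         f"{m.x_mean.size}")
    return (X_new - m.x_mean) @ m.regression_matrix + m.y_mean


def assign_classes(scores: np.ndarray, class_labels: list) -> np.ndarray:
    """Argmax class assignment; exact ties go to the first sorted class (logged)."""
    scores = np.atleast_2d(scores)
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 class-score columns")
    top = scores.max(axis=1, keepdims=True)
    ties = (scores == top).sum(axis=1) > 1
    for i in np.flatnonzero(ties):
        logger.warning("tied class scores in row %d; assigning first sorted class", i)
    idx = scores.argmax(axis=1)
    return np.asarray(class_labels)[idx]


def extract_band_vectors(m: PlsModel, wavelengths: np.ndarray) -> pd.DataFrame:
    """Wavelength-indexed LV loadings and per-class regression vectors.

    Columns: ``LV1`` ... ``LVk`` (X loadings) and ``regvec:<class>``.
    """
    cols = {}
    for a in range(m.effective_n_lv):
        cols[f"LV{a + 1}"] = m.x_loadings[:, a]
    for j, cls in enumerate(m.class_labels):
        cols[f"regvec:{cls}"] = m.regression_matrix[:, j]
    return pd.DataFrame(cols, index=np.asarray(wavelengths, float))


# -- cross-validation and metrics ------------------------------------------

@dataclass
class CvResult:
    """Fold assignment, out-of-fold predictions, and per-tier confusion counts."""

    folds: np.ndarray
    class_labels: list
    oof_scores: np.ndarray            # out-of-fold predicted indicator scores
    oof_labels: np.ndarray
    cal_scores: np.ndarray            # full-model fitted scores on calibration X
    cal_labels: np.ndarray
    true_labels: np.ndarray
    pred_scores: np.ndarray | None = None   # prediction-tier scores
    pred_labels: np.ndarray | None = None
    pred_true: np.ndarray | None = None
    warnings_: list = field(default_factory=list)

    def confusion(self, tier: str) -> pd.DataFrame:
        """One-vs-rest TP/FP/TN/FN counts per class for a tier."""
        true, pred = self._tier_labels(tier)
        rows = []
        for cls in self.class_labels:
            t = true == cls
            p = pred == cls
            rows.append({"class": cls,
                         "TP": int(np.sum(t & p)), "FP": int(np.sum(~t & p)),
                         "TN": int(np.sum(~t & ~p)), "FN": int(np.sum(t & ~p))})
        return pd.DataFrame(rows).set_index("class")

    def _tier_labels(self, tier: str):
        if tier == "calibration":
            return self.true_labels, self.cal_labels
        if tier == "cross_validation":
            return self.true_labels, self.oof_labels
        if tier == "prediction":
            if self.pred_labels is None:
                raise ValueError("no prediction tier in this CvResult")
            return self.pred_true, self.pred_labels
        raise ValueError(f"unknown tier {tier!r}")


def cross_validate(cal: SpectraSet, level: str, n_lv: int, k: int = 10,
                   steps: list[PptStep] | None = None,
                   pred: SpectraSet | None = None) -> tuple[PlsModel, CvResult]:
    """Venetian-blinds cross-validation with in-fold preprocessing.

    For every fold, the preprocessing statistics (MSC reference, column
    means) are re-fitted on the training portion only and replayed on the
    held-out fold; the full model (used for the calibration tier and for
    the optional prediction tier ``pred``) fits its statistics on the whole
    calibration set.
    """
    steps = steps or []
    labels = cal.groups(level).to_numpy()
    Y, classes = one_hot(labels)
    folds = venetian_blinds(cal.n_samples, k)
    warnings_: list[str] = []

    oof = np.full((cal.n_samples, len(classes)), np.nan)
    for f in range(k):
        hold = folds == f
        train_set, hold_set = cal.select(~hold), cal.select(hold)
        lost = [c for c in classes if c not in set(labels[~hold])]
        if lost:
            warnings_.append(f"fold {f}: training portion lost class(es) {lost}")
        pipe = Pipeline(steps)
        Xtr = pipe.fit_transform(train_set).absorbance
        Xho = pipe.transform(hold_set).absorbance
        Ytr, _ = one_hot(labels[~hold]) if not lost else (None, None)
        if lost:
            # keep column alignment with the full class set
            Ytr = (labels[~hold][:, None] == np.asarray(classes)[None, :]).astype(float)
        m = fit_pls2(Xtr, Ytr, min(n_lv, Xtr.shape[0] - 1), class_labels=classes)
        oof[hold] = predict(m, Xho)

    full_pipe = Pipeline(steps)
    Xcal = full_pipe.fit_transform(cal).absorbance
    model = fit_pls2(Xcal, Y, n_lv, class_labels=classes)
    cal_scores = predict(model, Xcal)

    result = CvResult(
        folds=folds, class_labels=classes,
        oof_scores=oof, oof_labels=assign_classes(oof, classes),
        cal_scores=cal_scores, cal_labels=assign_classes(cal_scores, classes),
        true_labels=labels, warnings_=warnings_)

    if pred is not None:
        Xp = full_pipe.transform(pred).absorbance
        ps = predict(model, Xp)
        result.pred_scores = ps
        result.pred_labels = assign_classes(ps, classes)
        result.pred_true = pred.groups(level).to_numpy()
    return model, result


def classification_metrics(cv: CvResult) -> pd.DataFrame:
    """Per-class, per-tier sensitivity, specificity and accuracy.

    One-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
    (TP+TN)/total.  Empty classes report NaN (undefined), never 0.
    """
    tiers = ["calibration", "cross_validation"]
    if cv.pred_labels is not None:
        tiers.append("prediction")
    rows = []
    for tier in tiers:
        conf = cv.confusion(tier)
        for cls, c in conf.iterrows():
            sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else np.nan
            spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else np.nan
            total = c.TP + c.TN + c.FP + c.FN
            acc = (c.TP + c.TN) / total if total else np.nan
            rows.append({"tier": tier, "class": cls, "n_class": int(c.TP + c.FN),
                         "sensitivity": sens, "specificity": spec, "accuracy": acc})
    return pd.DataFrame(rows)


def rmse_profile(cv: CvResult) -> pd.DataFrame:
    """Per-class RMSEC / RMSECV (/ RMSEP) on the indicator scale, plus ratios."""
    Y = (cv.true_labels[:, None] == np.asarray(cv.class_labels)[None, :]).astype(float)
    rows = []
    for j, cls in enumerate(cv.class_labels):
        rmsec = float(np.sqrt(np.mean((Y[:, j] - cv.cal_scores[:, j]) ** 2)))
        rmsecv = float(np.sqrt(np.mean((Y[:, j] - cv.oof_scores[:, j]) ** 2)))
        row = {"class": cls, "RMSEC": rmsec, "RMSECV": rmsecv,
               "RMSECV/RMSEC": rmsecv / rmsec if rmsec > 0 else np.nan}
        if cv.pred_scores is not None:
            Yp = (cv.pred_true[:, None] == np.asarray(cv.class_labels)[None, :]
                  ).astype(float)
            rmsep = float(np.sqrt(np.mean((Yp[:, j] - cv.pred_scores[:, j]) ** 2)))
            row["RMSEP"] = rmsep
            row["RMSEP/RMSECV"] = rmsep / rmsecv if rmsecv > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


# -- one-call classification workflow --------------------------------------

@dataclass
class ClassificationRun:
    level: str
    model: PlsModel
    cv: CvResult
    metrics: pd.DataFrame
    rmse: pd.DataFrame
    band_vectors: pd.DataFrame
    calibration_idx: np.ndarray
    prediction_idx: np.ndarray


def classify(s: SpectraSet, level: str, n_lv: int, k: int = 10,
             frac: float = 0.67, seed: int = 0,
             steps: list[PptStep] | None = None) -> ClassificationRun:
    """Full PLS-DA workflow: stratified 67/33 split, venetian-blinds CV,
    independent prediction, metrics, RMSE profile, and band vectors."""
    cal_idx, pred_idx = split_calibration_prediction(s, frac=frac, seed=seed)
    cal, pred = s.select(cal_idx), s.select(pred_idx)
    model, cv = cross_validate(cal, level, n_lv, k=k, steps=steps, pred=pred)
    return ClassificationRun(
        level=level, model=model, cv=cv,
        metrics=classification_metrics(cv), rmse=rmse_profile(cv),
        band_vectors=extract_band_vectors(model, s.wavelengths),
        calibration_idx=cal_idx, prediction_idx=pred_idx)
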