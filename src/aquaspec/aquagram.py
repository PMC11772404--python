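"""Aquagrams (water spectral patterns) and their statistics.

The aquagram displays, per sample group, the normalized absorbance
A'λ = (Aλ − μλ) / σλ at each of the twelve WAMACS, after multiplicative
scatter correction.  In the classic dataset-referenced construction, μλ and
σλ are the mean and sd over *all* samples in the dataset and a group's
value is the mean standardized value of its samples; the aquagram is thus a
relative construct that depends on the whole dataset.  A literal per-group
standardization (μλ, σλ from the group itself) is retained as a documented
warning path: it makes every group value identically zero.

Downstream statistics: PCA of the group × WAMAC matrix, Pearson
correlation between WAMACS across groups, WAMAC-versus-composition
correlation across chemovars, and a per-WAMAC one-way ANOVA on the
sample-level standardized values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import msc
from .spectra import CompositionTable, SpectraSet
from .wamacs import WamacsRegistry, default_registry


class AquagramError(ValueError):
    pass


@dataclass
class AquagramResult:
    level: str
    mode: str                      # "classic_dataset" | "per_group_literal"
    values: pd.DataFrame           # groups × WAMACS, normalized A'λ
    wavelengths_used: pd.Series    # WAMAC label -> grid wavelength actually used
    mu: pd.Series                  # μλ per WAMAC (dataset-wide in classic mode)
    sigma: pd.Series               # σλ per WAMAC
    n: pd.Series                   # samples per group
    sample_values: pd.DataFrame    # per-sample standardized values (classic scale)
    sample_groups: pd.Series       # group label per sample


def compute_aquagram(s: SpectraSet, level: str,
                     registry: WamacsRegistry | None = None,
                     mode: str = "classic_dataset",
                     apply_msc: bool = True,
                     window_nm: float = 0.0,
                     ddof: int = 0) -> AquagramResult:
    """Aquagram values per group at the twelve WAMACS.

    Spectra should already be cropped to the OH first overtone; MSC against
    the dataset mean is applied here unless ``apply_msc=False`` (pass False
    only if the input is already scatter-corrected).  Each WAMAC is read at
    the nearest grid wavelength (optionally averaged over ``window_nm``).
    σλ defaults to the population standard deviation (``ddof=0``), so two
    equal-sized groups sitting at ±d around the global mean score exactly ±1.
    """
    registry = registry or default_registry()
    if mode not in ("classic_dataset", "per_group_literal"):
        raise AquagramError(f"unknown aquagram mode {mode!r}")
    groups = s.groups(level)
    if apply_msc:
        s, _, _ = msc(s)
    X = s.absorbance

    cols, used = {}, {}
    for w in registry:
        if window_nm > 0:
            sel = np.abs(s.wavelengths - w.wavelength) <= window_nm / 2
            if not sel.any():
                sel = np.array([np.argmin(np.abs(s.wavelengths - w.wavelength))])
            vals = X[:, sel].mean(axis=1)
            used[w.label] = float(np.mean(s.wavelengths[sel]))
        else:
            i = int(np.argmin(np.abs(s.wavelengths - w.wavelength)))
            vals = X[:, i]
            used[w.label] = float(s.wavelengths[i])
        cols[w.label] = vals
    A = pd.DataFrame(cols)

    group_names = list(pd.unique(groups))
    if mode == "per_group_literal":
        warnings.warn(
            "per_group_literal aquagram mode standardizes each group by its own "
            "mean and sd: all group values are identically zero by construction. "
            "Use classic_dataset mode for an informative aquagram.")
        rows = {}
        for g in group_names:
            block = A[(groups == g).to_numpy()]
            sd = block.std(ddof=ddof)
            if (sd == 0).any():
                band = sd.index[(sd == 0).argmax()]
                raise AquagramError(f"σλ = 0 at WAMAC {band} within group {g!r}")
            rows[g] = ((block - block.mean()) / sd).mean()
        values = pd.DataFrame(rows).T
        mu = A.mean()
        sigma = A.std(ddof=ddof)
        z = (A - mu) / sigma
    else:
        mu = A.mean()
        sigma = A.std(ddof=ddof)
        if (sigma == 0).any():
            band = sigma.index[(sigma == 0).argmax()]
            raise AquagramError(f"σλ = 0 at WAMAC {band}: all samples identical there")
        z = (A - mu) / sigma
        values = z.groupby(groups.to_numpy()).mean().loc[group_names]

    n = A.groupby(groups.to_numpy()).size().loc[group_names]
    return AquagramResult(level=level, mode=mode, values=values,
                          wavelengths_used=pd.Series(used), mu=mu, sigma=sigma,
                          n=n, sample_values=z, sample_groups=groups)


# -- PCA -------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame       # groups × PCs
    loadings: pd.DataFrame     # WAMACS × PCs, orthonormal columns
    explained: np.ndarray      # % variance per PC


def aquagram_pca(a: AquagramResult) -> PcaResult:
    """SVD-based PCA of the column-centred group × WAMAC aquagram matrix."""
    M = a.values.to_numpy(float)
    if M.shape[0] < 2:
        raise AquagramError("PCA needs at least 2 groups")
    if M.shape[0] == 2:
        warnings.warn("only 2 groups: a single nontrivial principal component")
    C = M - M.mean(axis=0)
    U, sv, Vt = np.linalg.svd(C, full_matrices=False)
    scores = U * sv
    tot = np.sum(sv ** 2)
    explained = 100.0 * sv ** 2 / tot if tot > 0 else np.zeros_like(sv)
    pcs = [f"PC{i + 1}" for i in range(sv.size)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=a.values.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=a.values.columns, columns=pcs),
        explained=explained)


# -- correlation structure -------------------------------------------------

@dataclass
class CorrMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def _pearson_frame(X: pd.DataFrame, Y: pd.DataFrame) -> CorrMatrix:
    """Pairwise Pearson r between columns of X and columns of Y (aligned rows),
    with two-sided p-values from the t distribution on n − 2 df.  Pairs with a
    zero-variance column are reported as missing (NaN), never as 0."""
    rows_r, rows_p, rows_n = [], [], []
    for cx in X.columns:
        rr, pp, nn = {}, {}, {}
        for cy in Y.columns:
            x, y = X[cx].to_numpy(float), Y[cy].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            n = x.size
            nn[cy] = n
            if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                rr[cy], pp[cy] = np.nan, np.nan
                continue
            res = scipy.stats.pearsonr(x, y)
            rr[cy], pp[cy] = float(res.statistic), float(res.pvalue)
        rows_r.append(rr)
        rows_p.append(pp)
        rows_n.append(nn)
    idx = X.columns
    return CorrMatrix(r=pd.DataFrame(rows_r, index=idx),
                      p=pd.DataFrame(rows_p, index=idx),
                      n=pd.DataFrame(rows_n, index=idx))


def wamacs_correlation_matrix(a: AquagramResult) -> CorrMatrix:
    """Pearson r between WAMAC aquagram values across groups (square, symmetric)."""
    if len(a.values) < 3:
        raise AquagramError("WAMAC correlation needs at least 3 groups")
    cm = _pearson_frame(a.values, a.values)
    np.fill_diagonal(cm.r.values, 1.0)
    return cm


def composition_correlation(a: AquagramResult, comp: CompositionTable) -> CorrMatrix:
    """Pearson r between each WAMAC and each analyte across chemovars.

    The aquagram must be at chemovar level and its chemovar keys must all
    be present in the composition table.
    """
    missing = [g for g in a.values.index if g not in comp.data.index]
    if missing:
        raise AquagramError(f"chemovars missing from composition table: {missing}")
    if len(a.values) < 3:
        raise AquagramError("composition correlation needs at least 3 chemovars")
    C = comp.data.loc[a.values.index]
    return _pearson_frame(a.values, C)


def anova_per_wamac(sample_values: pd.DataFrame, groups: pd.Series,
                    min_group_size: int = 2) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across groups, one test per WAMAC.

    Groups smaller than ``min_group_size`` are excluded with a warning.
    Returns F and unadjusted p per WAMAC.
    """
    groups = pd.Series(np.asarray(groups))
    keep_names = []
    for g, cnt in groups.value_counts().items():
        if cnt < min_group_size:
            warnings.warn(f"group {g!r} has n={cnt} < {min_group_size}; excluded from ANOVA")
        else:
            keep_names.append(g)
    if len(keep_names) < 2:
        raise AquagramError("ANOVA needs at least 2 groups of sufficient size")
    rows = []
    for band in sample_values.columns:
        arrays = [sample_values.loc[(groups == g).to_numpy(), band].to_numpy()
                  for g in keep_names]
        F, p = scipy.stats.f_oneway(*arrays)
        rows.append({"wamac": band, "F": float(F), "p": float(p)})
    return pd.DataFrame(rows).set_index("wamac")


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional multiplicity control)."""
    p = p.astype(float)
    m = p.notna().sum()
    order = p.dropna().sort_values()
    adj = order * m / np.arange(1, m + 1)
    adj = adj[::-1].cummin()[::-1].clip(upper=1.0)
    out = pd.Series(np.nan, index=p.index)
    out.loc[adj.index] = adj
    return out
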