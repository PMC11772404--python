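"""Spectral preprocessing transformations (PPTs) and their composition.

Implements the standard NIR pre-treatment menu — Savitzky-Golay smoothing
and derivatives, multiplicative scatter correction (MSC), standard normal
variate (SNV), polynomial detrend, and mean centering — plus an ordered
pipeline with calibration/apply semantics: statistics fitted on calibration
data (the MSC reference spectrum, column means) are stored and replayed on
held-out data, never re-estimated from it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.signal

from .spectra import SpectraSet


class PreprocessError(ValueError):
    pass


@dataclass
class PptStep:
    """One named preprocessing step with its parameters.

    Names: ``savitzky_golay``, ``msc``, ``snv``, ``detrend``,
    ``mean_center``, ``normalize`` (unit-area row scaling).
    """

    name: str
    params: dict[str, Any] = field(default_factory=dict)

    _KNOWN = ("savitzky_golay", "msc", "snv", "detrend", "mean_center", "normalize")

    def __post_init__(self) -> None:
        if self.name not in self._KNOWN:
            raise PreprocessError(f"unknown PPT step {self.name!r}")
        if self.name == "savitzky_golay":
            w = self.params.get("window", 11)
            p = self.params.get("polyorder", 2)
            d = self.params.get("deriv", 0)
            if w % 2 == 0 or w <= p:
                raise PreprocessError(f"SG window must be odd and > polyorder (got {w}, {p})")
            if d > p:
                raise PreprocessError(f"SG deriv {d} exceeds polyorder {p}")


# -- individual transforms -------------------------------------------------

def savitzky_golay(s: SpectraSet, window: int = 11, polyorder: int = 2,
                   deriv: int = 0) -> SpectraSet:
    """Savitzky-Golay filter per spectrum (smoothing for ``deriv=0``).

    Derivatives are scaled by the grid step so units are per nm^deriv.
    Requires a uniform wavelength grid; edges are handled by fitting the
    edge-window polynomial and evaluating it (no reflection padding), which
    avoids fabricating absorbances beyond the measured 1300/1600 nm limits.
    """
    PptStep("savitzky_golay", {"window": window, "polyorder": polyorder, "deriv": deriv})
    if window >= s.n_wavelengths:
        raise PreprocessError(
            f"SG window {window} >= number of wavelengths {s.n_wavelengths}")
    steps = np.diff(s.wavelengths)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise PreprocessError("SG requires a uniform wavelength grid; resample first")
    out = scipy.signal.savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=float(steps[0]), axis=1, mode="interp")
    return s.with_absorbance(out)


def msc(s: SpectraSet, reference: np.ndarray | None = None,
        b_tol: float = 1e-8) -> tuple[SpectraSet, np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x_i is regressed on the reference, x_i = a_i + b_i * ref,
    and corrected to (x_i - a_i) / b_i.  Default reference is the mean
    spectrum of the set being corrected.  Returns (corrected, a, b) so the
    fitted scatter parameters can be audited.
    """
    if s.n_wavelengths < 2:
        raise PreprocessError("MSC needs at least 2 wavelengths")
    ref = s.absorbance.mean(axis=0) if reference is None else np.asarray(reference, float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise PreprocessError("MSC reference spectrum has zero variance")
    X = s.absorbance
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = X.mean(axis=1) - b * ref.mean()
    small = np.abs(b) < b_tol
    if small.any():
        bad = s.samples["sample_id"].iloc[np.flatnonzero(small)[0]]
        raise PreprocessError(f"degenerate MSC slope |b| < {b_tol} for sample {bad!r}")
    corrected = (X - a[:, None]) / b[:, None]
    return s.with_absorbance(corrected), a, b


def snv(s: SpectraSet, ddof: int = 1) -> SpectraSet:
    """Standard normal variate: each row centred and scaled by its own sd."""
    X = s.absorbance
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    zero = (sd.ravel() == 0)
    if zero.any():
        bad = s.samples["sample_id"].iloc[np.flatnonzero(zero)[0]]
        raise PreprocessError(f"SNV: zero-variance spectrum for sample {bad!r}")
    return s.with_absorbance((X - mu) / sd)


def detrend(s: SpectraSet, order: int = 1) -> SpectraSet:
    """Subtract the per-row least-squares polynomial of given order in λ."""
    if order < 0:
        raise PreprocessError("detrend order must be >= 0")
    if order >= s.n_wavelengths:
        raise PreprocessError(f"detrend order {order} >= n_wavelengths {s.n_wavelengths}")
    # centred/scaled λ for conditioning
    lam = s.wavelengths
    x = (lam - lam.mean()) / max(np.ptp(lam) / 2, 1.0)
    V = np.vander(x, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, s.absorbance.T, rcond=None)
    return s.with_absorbance(s.absorbance - (V @ coef).T)


def mean_center(s: SpectraSet,
                means: np.ndarray | None = None) -> tuple[SpectraSet, np.ndarray]:
    """Column mean-centering; returns the means so held-out data can reuse them."""
    m = s.absorbance.mean(axis=0) if means is None else np.asarray(means, float)
    return s.with_absorbance(s.absorbance - m), m


def normalize(s: SpectraSet) -> SpectraSet:
    """Scale each row to unit Euclidean norm."""
    norms = np.linalg.norm(s.absorbance, axis=1, keepdims=True)
    zero = (norms.ravel() == 0)
    if zero.any():
        bad = s.samples["sample_id"].iloc[np.flatnonzero(zero)[0]]
        raise PreprocessError(f"normalize: zero-norm spectrum for sample {bad!r}")
    return s.with_absorbance(s.absorbance / norms)


# -- pipeline with fit/apply semantics -------------------------------------

class Pipeline:
    """Ordered composition of PPT steps with calibration statistics.

    ``fit_transform`` learns any data-dependent statistics (MSC reference,
    column means) on the calibration set; ``transform`` replays the exact
    same statistics on held-out spectra so no information leaks from the
    prediction group into the model.
    """

    def __init__(self, steps: list[PptStep]):
        self.steps = [st if isinstance(st, PptStep) else PptStep(**st) for st in steps]
        self.fitted_: list[dict] | None = None

    def fit_transform(self, s: SpectraSet) -> SpectraSet:
        self.fitted_ = []
        for st in self.steps:
            state: dict[str, Any] = {}
            if st.name == "msc" and "reference" not in st.params:
                state["reference"] = s.absorbance.mean(axis=0)
                s, _, _ = msc(s, reference=state["reference"],
                              b_tol=st.params.get("b_tol", 1e-8))
            elif st.name == "mean_center":
                s, m = mean_center(s)
                state["means"] = m
            else:
                s = self._apply_stateless(s, st)
            self.fitted_.append(state)
        return s

    def transform(self, s: SpectraSet) -> SpectraSet:
        if self.fitted_ is None:
            raise PreprocessError("pipeline not fitted; call fit_transform first")
        for st, state in zip(self.steps, self.fitted_):
            if st.name == "msc" and "reference" in state:
                s, _, _ = msc(s, reference=state["reference"],
                              b_tol=st.params.get("b_tol", 1e-8))
            elif st.name == "mean_center":
                s, _ = mean_center(s, means=state["means"])
            else:
                s = self._apply_stateless(s, st)
        return s

    @staticmethod
    def _apply_stateless(s: SpectraSet, st: PptStep) -> SpectraSet:
        if st.name == "savitzky_golay":
            return savitzky_golay(s, **st.params)
        if st.name == "msc":  # explicit fixed reference supplied in params
            return msc(s, reference=np.asarray(st.params["reference"], float),
                       b_tol=st.params.get("b_tol", 1e-8))[0]
        if st.name == "snv":
            return snv(s, **st.params)
        if st.name == "detrend":
            return detrend(s, **st.params)
        if st.name == "normalize":
            return normalize(s)
        raise PreprocessError(f"unhandled step {st.name!r}")  # pragma: no cover

    def state_checksum(self) -> str:
        """Digest of all fitted statistics (leakage audits in tests)."""
        h = hashlib.sha256()
        for state in self.fitted_ or []:
            for key in sorted(state):
                h.update(key.encode())
                h.update(np.ascontiguousarray(state[key]).tobytes())
        return h.hexdigest()

    def describe(self) -> list[dict]:
        return [{"name": st.name,
                 "params": {k: v for k, v in st.params.items() if k != "reference"}}
                for st in self.steps]


def apply_pipeline(s: SpectraSet, steps: list[PptStep]) -> SpectraSet:
    """One-shot ordered composition (fits any statistics on ``s`` itself)."""
    return Pipeline(steps).fit_transform(s)


#: The model-development PPT the classification workflow defaults to:
#: MSC followed by smoothing.
MODEL_PPT = [PptStep("msc"), PptStep("savitzky_golay",
                                     {"window": 11, "polyorder": 2, "deriv": 0})]

#: The spectrum-exploration PPT: 2nd derivative, then MSC, then smoothing.
EXPLORATION_PPT = [
    PptStep("savitzky_golay", {"window": 15, "polyorder": 3, "deriv": 2}),
    PptStep("msc"),
    PptStep("savitzky_golay", {"window": 11, "polyorder": 2, "deriv": 0}),
]
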