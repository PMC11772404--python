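"""Seeded generator of wet-inflorescence-like NIR spectra.

Emulates the study design this package is built around: seven cannabis
chemovars in three major classes (621-17, Erez, 505, 240 high THCA; Gen12
hybrid; 156, 45-3 high CBDA) with per-chemovar sample counts
{21, 30, 25, 25, 30, 26, 30} (187 samples), four scans per sample, on a
1300-1600 nm grid.

Each underlying spectrum is a baseline plus twelve Gaussian water bands at
the WAMACS centres, with per-chemovar amplitude patterns, per-sample
amplitude jitter, multiplicative/additive scatter, and per-scan white
noise:

    A(λ) = m_i · [ b0 + b1·(λ−1300) + Σ_k α_ik · exp(−(λ−c_k)²/(2 σ_k²)) ]
           + o_i + ε_ir(λ)

    α_ik = a_gk + Σ_analyte β_k · z_i(analyte) + jitter

where z_i standardizes the sample's analyte value against the spread of
the designed chemovar means, so composition-band coupling is controlled at
the chemovar level (seven points), which is the level at which the
aquagram-composition correlations are computed.  The generator returns the
ground truth (realized amplitudes, scatter parameters, designed
correlations) so recovery tests can score every pipeline stage.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import CompositionTable, SpectraSet
from .wamacs import default_registry

MAJOR_CLASS_OF = {
    "621-17": "high_THCA", "Erez": "high_THCA", "505": "high_THCA",
    "240": "high_THCA", "Gen12": "hybrid", "156": "high_CBDA", "45-3": "high_CBDA",
}

#: Study-design sample counts per chemovar (total 187).
DEFAULT_COUNTS = {"621-17": 21, "Erez": 30, "505": 25, "240": 25,
                  "Gen12": 30, "156": 26, "45-3": 30}


class SimulationError(ValueError):
    pass


@dataclass
class ChemovarSpec:
    name: str
    major_class: str
    n_samples: int
    band_amplitudes: np.ndarray          # (12,) Gaussian amplitudes over C1-C12
    analytes: dict[str, float] = field(default_factory=dict)  # designed means, DW%


@dataclass
class SimulationConfig:
    chemovars: list[ChemovarSpec]
    wl_min: float = 1300.0
    wl_max: float = 1600.0
    wl_step: float = 2.0
    band_centers: np.ndarray = field(
        default_factory=lambda: np.asarray(default_registry().wavelengths))
    band_widths: np.ndarray = field(default_factory=lambda: np.full(12, 7.0))
    baseline_intercept: float = 0.55
    baseline_slope: float = 5e-4          # per nm
    scatter_mult_sd: float = 0.05         # m_i ~ Normal(1, s_m)
    scatter_add_sd: float = 0.02          # o_i ~ Normal(0, s_o)
    within_factor_loadings: np.ndarray = field(
        default_factory=lambda: DEFAULT_WITHIN_FACTORS.copy())
    within_factor_sd: float = 0.015       # per-sample water-state factor scores
    amplitude_jitter_sd: float = 0.001    # per-sample, per-band iid jitter
    noise_sd: float = 0.001               # per-scan white noise per wavelength
    n_replicates: int = 4                 # scans per sample
    replicate_noise_sd: float = 0.001     # per-scan scalar offset
    analyte_within_sd_frac: float = 0.05  # within-chemovar analyte sd, as a
                                          # fraction of the across-chemovar sd
    coupling: dict[str, np.ndarray] = field(default_factory=dict)  # analyte -> β (12,)
    designed_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, float)
        self.band_widths = np.asarray(self.band_widths, float)
        self.within_factor_loadings = np.atleast_2d(
            np.asarray(self.within_factor_loadings, float))
        self.validate()

    def validate(self) -> None:
        if not self.chemovars:
            raise SimulationError("at least one chemovar required")
        for cv in self.chemovars:
            if cv.n_samples <= 0:
                raise SimulationError(f"chemovar {cv.name!r} has non-positive count")
            if np.asarray(cv.band_amplitudes).size != self.band_centers.size:
                raise SimulationError(
                    f"chemovar {cv.name!r}: amplitude vector length mismatch")
        if np.any(self.band_widths <= 0):
            raise SimulationError("band widths must be positive")
        if self.scatter_mult_sd >= 0.5:
            raise SimulationError("multiplicative scatter sd must be < 0.5")
        for v in (self.scatter_mult_sd, self.scatter_add_sd, self.amplitude_jitter_sd,
                  self.noise_sd, self.replicate_noise_sd, self.analyte_within_sd_frac,
                  self.within_factor_sd):
            if v < 0:
                raise SimulationError("noise/scatter sds must be >= 0")
        if self.within_factor_loadings.shape[1] != self.band_centers.size:
            raise SimulationError("within-factor loadings must span the 12 bands")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_min, self.wl_max + self.wl_step / 2, self.wl_step)

    @property
    def total_samples(self) -> int:
        return sum(cv.n_samples for cv in self.chemovars)

    def analyte_names(self) -> list[str]:
        names: list[str] = []
        for cv in self.chemovars:
            for a in cv.analytes:
                if a not in names:
                    names.append(a)
        return names

    def chemovar_means(self, analyte: str) -> np.ndarray:
        return np.asarray([cv.analytes.get(analyte, 0.0) for cv in self.chemovars])

    def to_dict(self) -> dict:
        return {
            "wl_min": self.wl_min, "wl_max": self.wl_max, "wl_step": self.wl_step,
            "band_centers": self.band_centers.tolist(),
            "band_widths": self.band_widths.tolist(),
            "baseline_intercept": self.baseline_intercept,
            "baseline_slope": self.baseline_slope,
            "scatter_mult_sd": self.scatter_mult_sd,
            "scatter_add_sd": self.scatter_add_sd,
            "within_factor_loadings": self.within_factor_loadings.tolist(),
            "within_factor_sd": self.within_factor_sd,
            "amplitude_jitter_sd": self.amplitude_jitter_sd,
            "noise_sd": self.noise_sd,
            "n_replicates": self.n_replicates,
            "replicate_noise_sd": self.replicate_noise_sd,
            "analyte_within_sd_frac": self.analyte_within_sd_frac,
            "seed": self.seed,
            "coupling": {k: np.asarray(v).tolist() for k, v in self.coupling.items()},
            "designed_correlations": {f"{a}:{w}": r for (a, w), r
                                      in self.designed_correlations.items()},
            "chemovars": [{
                "name": cv.name, "major_class": cv.major_class,
                "n_samples": cv.n_samples,
                "band_amplitudes": np.asarray(cv.band_amplitudes).tolist(),
                "analytes": dict(cv.analytes)} for cv in self.chemovars],
        }


@dataclass
class SyntheticTruth:
    """Ground truth aligned 1:1 with the generated samples."""

    samples: pd.DataFrame        # sample_id, chemovar, major_class, m, o, analytes
    amplitudes: pd.DataFrame     # sample × C1..C12 realized band amplitudes
    designed_correlations: dict[tuple[str, str], float]


# -- default study design --------------------------------------------------

#: Two dominant within-sample water-state factors: loadings over C1-C12.
#: Real wet-tissue spectra vary sample-to-sample mostly along a few
#: collective water-structure modes rather than band-by-band; the factors
#: below encode (1) solvation-shell strength (C2-C4 up, C11/C12 down) and
#: (2) the free-versus-strongly-bound water balance (C5/C6 up, C11/C12 down).
DEFAULT_WITHIN_FACTORS = np.array([
    [0.3, 1.0, 0.8, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.4, -0.6, -0.4],
    [0.2, 0.0, 0.0, 0.0, 1.0, 0.6, 0.0, 0.2, 0.2, 0.0, -0.5, -1.0],
])


def _default_amplitudes() -> dict[str, np.ndarray]:
    # Common wet-plant water-band profile peaking near 1452 nm (C8), where the
    # raw-spectrum standard deviation is also largest in the emulated study.
    base = np.array([0.10, 0.14, 0.16, 0.18, 0.26, 0.30,
                     0.34, 0.36, 0.34, 0.30, 0.26, 0.18])
    deltas = {
        #           C1    C2    C3    C4    C5    C6    C7    C8    C9   C10   C11   C12
        "621-17": [+.03, +.03, 0.00, 0.00, +.06, +.03, 0.00, +.03, +.03, 0.00, 0.00, -.04],
        "Erez":   [0.00, -.02, 0.00, -.02, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, +.03, +.05],
        "505":    [0.00, 0.00, 0.00, 0.00, -.02, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, +.04],
        "240":    [0.00, +.02, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, -.01, +.04],
        "Gen12":  [0.00, 0.00, -.05, -.05, -.07, -.04, 0.00, 0.00, 0.00, 0.00, +.05, +.04],
        "156":    [0.00, +.06, +.06, +.06, 0.00, 0.00, 0.00, 0.00, 0.00, +.03, -.05, -.03],
        "45-3":   [0.00, +.01, +.03, +.03, 0.00, 0.00, 0.00, +.04, +.04, +.03, -.02, -.03],
    }
    # deltas scaled 1.5x so every between-class contrast is at least ~5x the
    # within-class amplitude noise along the separating direction
    return {name: base + 1.5 * np.asarray(d) for name, d in deltas.items()}


#: Designed chemovar-mean compositions (DW%).  CBGA is ordered inversely with
#: the C5 (free water) amplitudes and positively with C12 (strongly bound
#: water); guaiol follows the C2-C4 solvation-shell amplitudes.
DEFAULT_COMPOSITION = {
    #            THCA  CBDA  CBGA  guaiol  alpha_pinene  beta_myrcene  wet_water_pct
    "621-17": dict(THCA=20.0, CBDA=0.30, CBGA=0.20, guaiol=0.030,
                   alpha_pinene=0.25, beta_myrcene=0.50, wet_water_pct=77.0),
    "Erez":   dict(THCA=19.0, CBDA=0.30, CBGA=1.20, guaiol=0.008,
                   alpha_pinene=0.10, beta_myrcene=0.30, wet_water_pct=76.0),
    "505":    dict(THCA=18.0, CBDA=0.20, CBGA=1.10, guaiol=0.010,
                   alpha_pinene=0.12, beta_myrcene=0.60, wet_water_pct=78.0),
    "240":    dict(THCA=21.0, CBDA=0.30, CBGA=1.00, guaiol=0.012,
                   alpha_pinene=0.30, beta_myrcene=0.40, wet_water_pct=75.0),
    "Gen12":  dict(THCA=7.0, CBDA=6.50, CBGA=0.90, guaiol=0.006,
                   alpha_pinene=0.08, beta_myrcene=0.70, wet_water_pct=79.0),
    "156":    dict(THCA=0.60, CBDA=13.0, CBGA=0.35, guaiol=0.060,
                   alpha_pinene=0.15, beta_myrcene=0.20, wet_water_pct=76.0),
    "45-3":   dict(THCA=0.50, CBDA=12.5, CBGA=0.40, guaiol=0.040,
                   alpha_pinene=0.20, beta_myrcene=0.45, wet_water_pct=78.0),
}


def default_cannabis_config(seed: int = 0) -> SimulationConfig:
    """The seven-chemovar, 187-sample default study design.

    Band-amplitude patterns are qualitative mimics of the emulated study's
    reported orderings: elevated C5 (free water) for 621-17, elevated C2-C4
    (solvation shells) for 156, elevated C12 (strongly bound water) for
    Erez/505/240/Gen12.  Between-group amplitude separation is at least 5x
    the within-group amplitude jitter.
    """
    amps = _default_amplitudes()
    chemovars = [ChemovarSpec(name=name, major_class=MAJOR_CLASS_OF[name],
                              n_samples=DEFAULT_COUNTS[name],
                              band_amplitudes=amps[name],
                              analytes=dict(DEFAULT_COMPOSITION[name]))
                 for name in DEFAULT_COUNTS]
    return SimulationConfig(chemovars=chemovars, seed=seed)


# -- generation ------------------------------------------------------------

def simulate_spectraset(config: SimulationConfig
                        ) -> tuple[SpectraSet, CompositionTable, SyntheticTruth]:
    """Generate spectra, per-chemovar composition table, and ground truth.

    Deterministic under ``config.seed``: the same config yields bit-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    labels = [f"C{i + 1}" for i in range(config.band_centers.size)]
    gauss = np.exp(-0.5 * ((wl[None, :] - config.band_centers[:, None])
                           / config.band_widths[:, None]) ** 2)  # (12, p)
    baseline = config.baseline_intercept + config.baseline_slope * (wl - config.wl_min)

    analytes = config.analyte_names()
    # chemovar-level standardization constants per analyte
    std_consts = {}
    for a in analytes:
        means = config.chemovar_means(a)
        mu = means.mean()
        sd = means.std(ddof=1) if len(means) > 1 else 0.0
        std_consts[a] = (mu, sd)

    rows, meta, truth_rows, amp_rows = [], [], [], []
    for cv in config.chemovars:
        a_g = np.asarray(cv.band_amplitudes, float)
        for j in range(cv.n_samples):
            sid = f"{cv.name}-s{j + 1:02d}"
            sample_analytes = {}
            alpha = a_g.copy()
            for a in analytes:
                mu, sd = std_consts[a]
                val = cv.analytes.get(a, 0.0) + config.analyte_within_sd_frac * sd \
                    * rng.standard_normal()
                sample_analytes[a] = val
                beta = config.coupling.get(a)
                if beta is not None and sd > 0:
                    alpha = alpha + np.asarray(beta, float) * (val - mu) / sd
            factor_scores = config.within_factor_sd * rng.standard_normal(
                config.within_factor_loadings.shape[0])
            alpha = alpha + factor_scores @ config.within_factor_loadings
            alpha = alpha + config.amplitude_jitter_sd * rng.standard_normal(alpha.size)
            m_i = 1.0 + config.scatter_mult_sd * rng.standard_normal()
            o_i = config.scatter_add_sd * rng.standard_normal()
            clean = baseline + alpha @ gauss
            for r in range(config.n_replicates):
                eps = (config.replicate_noise_sd * rng.standard_normal()
                       + config.noise_sd * rng.standard_normal(wl.size))
                rows.append(m_i * clean + o_i + eps)
                meta.append({"sample_id": sid, "chemovar": cv.name,
                             "major_class": cv.major_class,
                             "replicate_index": j + 1, "scan_index": r + 1})
            truth_rows.append({"sample_id": sid, "chemovar": cv.name,
                               "major_class": cv.major_class, "m": m_i, "o": o_i,
                               **sample_analytes})
            amp_rows.append(alpha)

    spectra = SpectraSet(wl, np.vstack(rows), pd.DataFrame(meta))
    comp = CompositionTable(pd.DataFrame(
        {a: config.chemovar_means(a) for a in analytes},
        index=pd.Index([cv.name for cv in config.chemovars], name="chemovar")))
    truth = SyntheticTruth(
        samples=pd.DataFrame(truth_rows),
        amplitudes=pd.DataFrame(np.vstack(amp_rows), columns=labels,
                                index=[t["sample_id"] for t in truth_rows]),
        designed_correlations=dict(config.designed_correlations))
    return spectra, comp, truth


# -- planted composition-band coupling -------------------------------------

def planted_correlation_config(base: SimulationConfig, analyte: str, wamac: str,
                               r_target: float) -> SimulationConfig:
    """Config whose designed chemovar-level correlation between an analyte
    and one WAMAC amplitude equals ``r_target``.

    Closed form from variance components: let z be the analyte's chemovar
    means standardized across chemovars, and a the base amplitudes at the
    WAMAC.  Decompose a = mean + c·z + e with e ⊥ z.  The planted config
    replaces the amplitude column with mean + e (removing the incidental
    correlation) and sets the coupling coefficient

        β = r·σ_e / sqrt(1 − r²)

    so the designed amplitudes mean + e + β·z correlate exactly r with the
    chemovar means.  Jitter/noise attenuate the realized correlation only
    through chemovar-mean noise of order jitter/sqrt(n_g), which is
    negligible at the default design.
    """
    if not abs(r_target) < 1:
        raise SimulationError("attainable designed correlations satisfy |r| < 1")
    labels = [f"C{i + 1}" for i in range(base.band_centers.size)]
    if wamac not in labels:
        raise SimulationError(f"unknown WAMAC label {wamac!r}")
    k = labels.index(wamac)
    means = base.chemovar_means(analyte)
    G = means.size
    sd = means.std(ddof=1)
    if sd == 0:
        raise SimulationError(f"analyte {analyte!r} is constant across chemovars; "
                              "no correlation can be planted")
    z = (means - means.mean()) / sd                      # sample sd 1, mean 0
    a = np.asarray([cv.band_amplitudes[k] for cv in base.chemovars], float)
    a_c = a - a.mean()
    c = (a_c @ z) / (z @ z)
    e = a_c - c * z
    sigma_e = np.sqrt((e @ e) / (G - 1))
    if sigma_e == 0 and r_target != 0:
        raise SimulationError(
            "base amplitudes are collinear with the analyte at this WAMAC; "
            "attainable designed correlations are only 0 or ±1")
    beta_k = r_target * sigma_e / np.sqrt(1 - r_target ** 2)

    cfg = copy.deepcopy(base)
    for cv, new_amp in zip(cfg.chemovars, a.mean() + e):
        amps = np.asarray(cv.band_amplitudes, float).copy()
        amps[k] = new_amp
        cv.band_amplitudes = amps
    beta = np.asarray(cfg.coupling.get(analyte, np.zeros(len(labels))), float).copy()
    beta[k] = beta_k
    cfg.coupling[analyte] = beta
    cfg.designed_correlations[(analyte, wamac)] = r_target
    return cfg


# -- serialization helpers --------------------------------------------------

def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "samples": truth.samples.to_dict(orient="records"),
        "amplitudes": {sid: row.tolist()
                       for sid, row in truth.amplitudes.iterrows()},
        "designed_correlations": {f"{a}:{w}": r for (a, w), r
                                  in truth.designed_correlations.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
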