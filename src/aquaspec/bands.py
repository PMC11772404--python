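"""Activated-water-band discovery.

Bands are read from two kinds of wavelength-indexed vectors: second
derivative preprocessed group-mean spectra (spectrum exploration) and
PLS-DA latent-variable loadings / regression vectors.  Local extrema with
sufficient prominence become :class:`BandHit`s, hits are assigned to the
nearest WAMAC, and a consistency tally over all sources identifies the
bands that recur across the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
import scipy.signal

from .wamacs import WamacsRegistry


@dataclass
class BandHit:
    source: str           # e.g. "exploration:<group>", "major_class:LV1", "chemovar:regvec:156"
    wavelength: float     # nm, on the analysis grid
    magnitude: float      # signed value of the vector at the extremum
    wamac: str | None = None   # assigned label, or None for unassigned


@dataclass
class ConsistencyTally:
    """Per WAMAC: the distinct sources in which it was detected."""

    sources: dict[str, set] = field(default_factory=dict)  # label -> {source, ...}

    def count(self, label: str) -> int:
        return len(self.sources.get(label, ()))

    def as_frame(self, registry: WamacsRegistry) -> pd.DataFrame:
        rows = [{"wamac": lab, "wavelength_nm": w, "n_sources": self.count(lab),
                 "sources": ";".join(sorted(self.sources.get(lab, ())))}
                for lab, w in zip(registry.labels, registry.wavelengths)]
        return pd.DataFrame(rows).set_index("wamac")


def detect_extrema(wavelengths: np.ndarray, v: np.ndarray, source: str = "",
                   prominence: float | None = None,
                   magnitude_floor: float | None = None) -> list[BandHit]:
    """Local maxima and minima of a vector whose prominence exceeds a threshold.

    Default prominence is 10% of max |v|.  Extrema whose absolute value
    falls below ``magnitude_floor`` (default: the same 10% threshold) are
    discarded: band reading keeps only the highest positive or negative
    contributions, not the near-zero saddles between two strong bands.
    Hits are returned sorted by wavelength, carrying the signed magnitude
    at the extremum.
    """
    v = np.asarray(v, float)
    wavelengths = np.asarray(wavelengths, float)
    if v.size < 3:
        raise ValueError("vector must have at least 3 points")
    if prominence is None:
        prominence = 0.1 * np.max(np.abs(v))
    if prominence < 0:
        raise ValueError("prominence must be >= 0")
    if magnitude_floor is None:
        magnitude_floor = 0.1 * np.max(np.abs(v))
    peaks_hi, _ = scipy.signal.find_peaks(v, prominence=prominence)
    peaks_lo, _ = scipy.signal.find_peaks(-v, prominence=prominence)
    idx = np.sort(np.concatenate([peaks_hi, peaks_lo]))
    idx = idx[np.abs(v[idx]) >= magnitude_floor]
    return [BandHit(source=source, wavelength=float(wavelengths[i]),
                    magnitude=float(v[i])) for i in idx]


def assign_wamacs(hits: list[BandHit], registry: WamacsRegistry,
                  tol: float = 6.0) -> list[BandHit]:
    """Assign each hit to a WAMAC (range membership, else nearest within tol)."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    out = []
    for h in hits:
        w = registry.nearest(h.wavelength, tol)
        out.append(BandHit(h.source, h.wavelength, h.magnitude,
                           w.label if w is not None else None))
    return out


def consistency_tally(hit_sets: list[tuple[str, list[BandHit]]]) -> ConsistencyTally:
    """Distinct-source count per WAMAC (duplicates within one source collapse)."""
    if not hit_sets:
        raise ValueError("need at least one source")
    tally = ConsistencyTally()
    for source, hits in hit_sets:
        for h in hits:
            if h.wamac is not None:
                tally.sources.setdefault(h.wamac, set()).add(source)
    return tally


def consistent_bands(tally: ConsistencyTally, registry: WamacsRegistry,
                     min_sources: int | None = None, n_sources: int | None = None
                     ) -> list[str]:
    """WAMACS detected in at least ``min_sources`` distinct sources, in C-order.

    Default threshold is a majority: ceil(n_sources / 2) when the total
    number of sources is supplied.
    """
    if min_sources is None:
        if n_sources is None:
            raise ValueError("provide min_sources or n_sources")
        min_sources = ceil(n_sources / 2)
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    return [lab for lab in registry.labels if tally.count(lab) >= min_sources]


def hits_frame(hits: list[BandHit]) -> pd.DataFrame:
    """Flat table of hits (source, wavelength, magnitude, WAMAC)."""
    return pd.DataFrame([{"source": h.source, "wavelength_nm": h.wavelength,
                          "magnitude": h.magnitude,
                          "wamac": h.wamac or "unassigned"} for h in hits])
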