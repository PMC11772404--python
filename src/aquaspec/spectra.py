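"""Data model and I/O for NIR reflectance spectra.

Spectra are stored as absorbance-like log(1/R) values on a strictly
ascending wavelength grid in nm, together with a per-sample metadata table
(chemovar, major class, replicate/scan indices).  All downstream analysis
in this package is restricted to the first overtone of the OH stretching
band (1300-1600 nm), but the container itself is range-agnostic.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Metadata columns recognised in wide-format spectra CSVs, in canonical order.
METADATA_COLUMNS = ("sample_id", "chemovar", "major_class", "replicate_index", "scan_index")

#: The three major cannabinoid classes.
MAJOR_CLASSES = ("high_THCA", "high_CBDA", "hybrid")


class SpectraFormatError(ValueError):
    """Raised when a spectra file or table violates the wide-CSV contract."""


class SpectraIntegrityError(ValueError):
    """Raised when a spectra table violates a structural invariant."""


@dataclass
class SpectraSet:
    """A set of NIR spectra on a shared wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly ascending wavelength grid in nm, shape ``(p,)``.
    absorbance
        log(1/R) matrix, shape ``(n_samples, p)``; all values finite.
    samples
        Per-row metadata table with at least ``sample_id``.  Optional
        columns: ``chemovar``, ``major_class``, ``replicate_index``,
        ``scan_index``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, self.wavelengths.size)
        self.samples = self.samples.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise SpectraIntegrityError(
                f"absorbance has {self.absorbance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.absorbance.shape[0] != len(self.samples):
            raise SpectraIntegrityError(
                f"absorbance has {self.absorbance.shape[0]} rows but the sample "
                f"table has {len(self.samples)}"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraIntegrityError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraIntegrityError("absorbance contains non-finite values")
        if "sample_id" not in self.samples.columns:
            raise SpectraIntegrityError("sample table must contain a 'sample_id' column")
        key = ["sample_id"] + (["scan_index"] if "scan_index" in self.samples else [])
        if self.samples.duplicated(subset=key).any():
            dupes = self.samples.loc[self.samples.duplicated(subset=key), key]
            raise SpectraIntegrityError(f"duplicate {key} rows: {dupes.values.tolist()[:5]}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Return a copy carrying a new absorbance matrix on the same grid."""
        return SpectraSet(self.wavelengths.copy(), np.asarray(absorbance, float),
                          self.samples.copy())

    def select(self, mask: np.ndarray) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectraSet(self.wavelengths.copy(), self.absorbance[idx],
                          self.samples.iloc[idx].reset_index(drop=True))

    def groups(self, level: str) -> pd.Series:
        if level not in self.samples.columns:
            raise SpectraIntegrityError(f"grouping column {level!r} not present")
        return self.samples[level]


@dataclass
class GroupSpectra:
    """Per-group mean and standard-deviation spectra."""

    level: str
    group_names: list
    wavelengths: np.ndarray
    mean: np.ndarray        # (n_groups, p)
    sd: np.ndarray          # (n_groups, p)
    n: np.ndarray           # samples per group

    def as_frame(self, which: str = "mean") -> pd.DataFrame:
        arr = self.mean if which == "mean" else self.sd
        return pd.DataFrame(arr, index=self.group_names, columns=self.wavelengths)


@dataclass
class CompositionTable:
    """Per-chemovar analyte concentrations in dry-weight percent.

    One row per chemovar; columns are analyte names (e.g. THCA, CBDA, CBGA,
    guaiol, alpha_pinene) plus an optional ``wet_water_pct``.
    """

    data: pd.DataFrame  # index: chemovar; columns: analytes (DW%)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise SpectraIntegrityError("composition table has duplicate chemovar rows")
        numeric = self.data.select_dtypes(include=[np.number])
        if (numeric.values < 0).any():
            raise SpectraIntegrityError("composition values must be non-negative")

    @property
    def chemovars(self) -> list:
        return list(self.data.index)

    @property
    def analytes(self) -> list:
        return list(self.data.columns)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CompositionTable":
        df = pd.read_csv(path, index_col="chemovar")
        return cls(df)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="chemovar", float_format="%.12g")


# -- I/O -------------------------------------------------------------------

def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a wide-format spectra CSV.

    Header: metadata column names (any subset of ``METADATA_COLUMNS``,
    ``sample_id`` mandatory) followed by numeric wavelength labels in nm.
    Wavelength columns may appear in any order; they are sorted ascending.
    """
    df = pd.read_csv(path)
    meta_cols, wl_cols, wl_vals = [], [], []
    for col in df.columns:
        if col in METADATA_COLUMNS:
            meta_cols.append(col)
            continue
        try:
            wl_vals.append(float(col))
            wl_cols.append(col)
        except ValueError:
            raise SpectraFormatError(
                f"column {col!r} is neither a known metadata column nor a numeric "
                "wavelength label"
            ) from None
    if "sample_id" not in meta_cols:
        raise SpectraFormatError("missing mandatory 'sample_id' column")
    order = np.argsort(wl_vals)
    wavelengths = np.asarray(wl_vals, float)[order]
    absorbance = df[wl_cols].to_numpy(float)[:, order]
    return SpectraSet(wavelengths, absorbance, df[meta_cols])


def write_spectra_csv(s: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as wide CSV, re-readable losslessly.

    Absorbance is written with 17 significant digits so a read/write
    round-trip preserves float64 values exactly.
    """
    meta = s.samples.copy()
    spec = pd.DataFrame(s.absorbance, columns=[f"{w:g}" for w in s.wavelengths])
    out = pd.concat([meta.reset_index(drop=True), spec], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")


# -- transformations -------------------------------------------------------

def crop_wavelengths(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict to the closed wavelength interval ``[lo, hi]`` nm."""
    if not lo < hi:
        raise ValueError(f"require lo < hi, got [{lo}, {hi}]")
    keep = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no wavelengths in range [{lo}, {hi}] nm")
    return SpectraSet(s.wavelengths[keep], s.absorbance[:, keep], s.samples.copy())


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Collapse repeated scans: one row per sample_id, mean absorbance.

    Requires a ``scan_index`` column.  The number of scans averaged is
    recorded in an ``n_scans`` metadata column; ``scan_index`` is dropped.
    """
    if "scan_index" not in s.samples.columns:
        raise SpectraIntegrityError("average_replicates requires a 'scan_index' column")
    df = s.samples.copy()
    df["_row"] = np.arange(len(df))
    rows_out, meta_rows = [], []
    for sid, grp in df.groupby("sample_id", sort=False):
        rows_out.append(s.absorbance[grp["_row"].to_numpy()].mean(axis=0))
        meta = grp.iloc[0].drop(labels=["_row", "scan_index"]).copy()
        meta["n_scans"] = len(grp)
        meta_rows.append(meta)
    return SpectraSet(s.wavelengths.copy(), np.vstack(rows_out),
                      pd.DataFrame(meta_rows).reset_index(drop=True))


def group_mean_sd(s: SpectraSet, level: str | None, ddof: int = 1) -> GroupSpectra:
    """Per-group mean and sd spectra.

    ``level`` is a metadata column (``major_class`` or ``chemovar``) or
    ``None`` for a single overall group.  Default sd is the sample sd
    (``ddof=1``); groups of size 1 report sd 0 with a warning.
    """
    if level is None:
        labels = pd.Series(["all"] * s.n_samples)
        lvl_name = "all"
    else:
        labels = s.groups(level)
        lvl_name = level
    names, means, sds, ns = [], [], [], []
    for name in pd.unique(labels):
        block = s.absorbance[(labels == name).to_numpy()]
        names.append(name)
        means.append(block.mean(axis=0))
        ns.append(block.shape[0])
        if block.shape[0] <= ddof:
            warnings.warn(f"group {name!r} has n={block.shape[0]}; sd reported as 0")
            sds.append(np.zeros(s.n_wavelengths))
        else:
            sds.append(block.std(axis=0, ddof=ddof))
    return GroupSpectra(lvl_name, names, s.wavelengths.copy(),
                        np.vstack(means), np.vstack(sds), np.asarray(ns))


def resample_uniform(s: SpectraSet, step: float = 2.0) -> SpectraSet:
    """Linear-interpolate onto a uniform grid (needed before SG filters).

    If the existing grid is already uniform with the requested step the set
    is returned unchanged.
    """
    diffs = np.diff(s.wavelengths)
    if diffs.size and np.allclose(diffs, step, atol=1e-9):
        return s
    new_wl = np.arange(s.wavelengths[0], s.wavelengths[-1] + step / 2, step)
    new_abs = np.vstack([np.interp(new_wl, s.wavelengths, row) for row in s.absorbance])
    return SpectraSet(new_wl, new_abs, s.samples.copy())
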