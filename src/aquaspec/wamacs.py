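"""The twelve Water Matrix Coordinates (WAMACS) of the OH first overtone.

Aquaphotomics reads the 1300-1600 nm region through twelve characteristic
water absorbance bands, C1-C12, each attributed to a water species: free
water, water dimers, solvation shells, and water molecules carrying one to
four hydrogen bonds.  The registry stores one canonical aquagram wavelength
per band; observed band positions are matched to the registry by nearest
wavelength within a tolerance, because reported positions for the same
coordinate vary between analyses (e.g. C5 near 1404-1412 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Canonical aquagram wavelengths (nm) and physical annotations, C1-C12.
DEFAULT_WAMACS = [
    ("C1", 1342.0, "water solvation shell / free OH-"),
    ("C2", 1364.0, "water solvation shell (small solutes)"),
    ("C3", 1374.0, "symmetric + asymmetric stretch (v1 + v3)"),
    ("C4", 1384.0, "water solvation shell / superoxide hydration"),
    ("C5", 1412.0, "free water molecules"),
    ("C6", 1426.0, "water hydration (H-OH bend + bonds)"),
    ("C7", 1440.0, "water molecules with 1 hydrogen bond"),
    ("C8", 1452.0, "water molecules with 2 hydrogen bonds / hydration"),
    ("C9", 1462.0, "water molecules with 2 hydrogen bonds"),
    ("C10", 1476.0, "water molecules with 3 hydrogen bonds"),
    ("C11", 1488.0, "water molecules with 4 hydrogen bonds / dimers"),
    ("C12", 1512.0, "strongly bound water"),
]


@dataclass
class Wamac:
    label: str
    wavelength: float               # canonical aquagram wavelength, nm
    annotation: str = ""
    lo: float | None = None         # optional band range, nm
    hi: float | None = None

    def contains(self, wl: float) -> bool:
        return self.lo is not None and self.hi is not None and self.lo <= wl <= self.hi


@dataclass
class WamacsRegistry:
    """Exactly twelve WAMACS with strictly increasing wavelengths in 1300-1600 nm."""

    entries: list[Wamac] = field(
        default_factory=lambda: [Wamac(*e) for e in DEFAULT_WAMACS])

    def __post_init__(self) -> None:
        if len(self.entries) != 12:
            raise ValueError(f"registry must hold exactly 12 WAMACS, got {len(self.entries)}")
        wls = [e.wavelength for e in self.entries]
        if any(b <= a for a, b in zip(wls, wls[1:])):
            raise ValueError("WAMACS wavelengths must be strictly increasing")
        if min(wls) < 1300 or max(wls) > 1600:
            raise ValueError("WAMACS must lie within 1300-1600 nm")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    @property
    def wavelengths(self) -> list[float]:
        return [e.wavelength for e in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, label: str) -> Wamac:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def nearest(self, wl: float, tol: float) -> Wamac | None:
        """Match a wavelength: inside a declared range first, else nearest
        canonical wavelength within ``tol`` nm, else None."""
        for e in self.entries:
            if e.contains(wl):
                return e
        best = min(self.entries, key=lambda e: abs(e.wavelength - wl))
        return best if abs(best.wavelength - wl) <= tol else None

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = [{"label": e.label, "wavelength": e.wavelength,
                 "annotation": e.annotation, "lo": e.lo, "hi": e.hi}
                for e in self.entries]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WamacsRegistry":
        data = yaml.safe_load(Path(path).read_text())
        return cls([Wamac(**d) for d in data])


def default_registry() -> WamacsRegistry:
    """The registry with the canonical C1-C12 aquagram wavelengths."""
    return WamacsRegistry()
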