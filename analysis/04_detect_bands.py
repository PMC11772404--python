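#!/usr/bin/env python
"""Activated-water-band discovery and consistency tally.

Combines the exploration-stage band hits with extrema of the PLS-DA latent
variable loadings and regression vectors (both classification levels),
assigns every hit to a WAMAC, and tallies in how many distinct sources each
of the twelve coordinates recurs.  Bands detected in a majority of sources
are reported as the consistently activated set.
"""

import sys
from pathlib import Path

import pandas as pd

from aquaspec import (BandHit, assign_wamacs, consistency_tally,
                      consistent_bands, default_registry, detect_extrema)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "bands"


def main() -> None:
    expl_csv = ROOT / "exploration" / "exploration_band_hits.csv"
    OUT.mkdir(parents=True, exist_ok=True)
    reg = default_registry()

    sources: list[tuple[str, list[BandHit]]] = []
    if expl_csv.exists():
        df = pd.read_csv(expl_csv)
        for src, grp in df.groupby("source"):
            hits = [BandHit(src, r.wavelength_nm, r.magnitude,
                            None if r.wamac == "unassigned" else r.wamac)
                    for r in grp.itertuples()]
            sources.append((src, hits))
    else:
        sys.exit("run 02_explore_spectra.py first")

    for level in ("major_class", "chemovar"):
        vec_csv = ROOT / "classification" / f"band_vectors_{level}.csv"
        if not vec_csv.exists():
            sys.exit("run 03_classify_plsda.py first")
        vecs = pd.read_csv(vec_csv, index_col="wavelength_nm")
        for col in vecs.columns:
            src = f"{level}:{col}"
            hits = assign_wamacs(detect_extrema(vecs.index.to_numpy(),
                                                vecs[col].to_numpy(), source=src),
                                 reg)
            sources.append((src, hits))

    tally = consistency_tally(sources)
    tally_df = tally.as_frame(reg)
    tally_df.to_csv(OUT / "band_tally.csv")
    consistent = consistent_bands(tally, reg, n_sources=len(sources))
    (OUT / "consistent_bands.txt").write_text("\n".join(consistent) + "\n")

    print(f"{len(sources)} sources (exploration group means + LV loadings + "
          "regression vectors)")
    print(tally_df["n_sources"].to_string())
    print(f"consistently activated bands (majority of sources): {consistent}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    sys.exit(main())
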