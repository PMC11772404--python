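#!/usr/bin/env python
"""Spectrum exploration over the OH first overtone.

Replicate-averages and crops the simulated spectra, computes group mean and
standard-deviation spectra (major classes and chemovars), applies the
exploration preprocessing (2nd derivative, then MSC, then smoothing), and
reads activated water bands from the preprocessed group means.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from aquaspec import (EXPLORATION_PPT, apply_pipeline, assign_wamacs,
                      average_replicates, crop_wavelengths, default_registry,
                      detect_extrema, group_mean_sd, hits_frame,
                      read_spectra_csv)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "exploration"


def main() -> None:
    spectra_csv = ROOT / "data" / "spectra.csv"
    if not spectra_csv.exists():
        sys.exit("run 01_simulate_dataset.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    s = crop_wavelengths(average_replicates(read_spectra_csv(spectra_csv)),
                         1300, 1600)
    reg = default_registry()
    all_hits = []
    for level in ("major_class", "chemovar"):
        gs = group_mean_sd(s, level)
        gs.as_frame("mean").to_csv(OUT / f"raw_mean_{level}.csv")
        gs.as_frame("sd").to_csv(OUT / f"raw_sd_{level}.csv")
        sd_peak = gs.wavelengths[np.argmax(gs.sd.mean(axis=0))]
        print(f"[{level}] largest raw-spectrum sd near {sd_peak:.0f} nm")

        pre = apply_pipeline(s, EXPLORATION_PPT)
        gp = group_mean_sd(pre, level)
        gp.as_frame("mean").to_csv(OUT / f"preprocessed_mean_{level}.csv")
        for gname, row in zip(gp.group_names, gp.mean):
            hits = assign_wamacs(detect_extrema(gp.wavelengths, row,
                                                source=f"exploration:{gname}"), reg)
            all_hits.extend(hits)

    hits = hits_frame(all_hits)
    hits.to_csv(OUT / "exploration_band_hits.csv", index=False)
    found = sorted(set(hits.wamac) - {"unassigned"},
                   key=lambda l: int(l[1:]))
    print(f"activated water bands in preprocessed group means: {found}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    sys.exit(main())
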