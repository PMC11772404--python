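#!/usr/bin/env python
"""PLS-DA classification of major classes and chemovars.

Stratified 67/33 calibration/prediction split, MSC + smoothing, SIMPLS
PLS-DA (8 latent variables for the three major classes, 7 for the seven
chemovars), venetian-blinds cross-validation with 10 splits.  Emits
per-class sensitivity/specificity/accuracy for all three tiers and the
RMSEC/RMSECV/RMSEP profile with over-fitting ratios.
"""

import sys
from pathlib import Path

import numpy as np

from aquaspec import (MODEL_PPT, average_replicates, classify,
                      crop_wavelengths, read_spectra_csv)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "classification"
SEED = 0


def main() -> None:
    spectra_csv = ROOT / "data" / "spectra.csv"
    if not spectra_csv.exists():
        sys.exit("run 01_simulate_dataset.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    s = crop_wavelengths(average_replicates(read_spectra_csv(spectra_csv)),
                         1300, 1600)
    for level, n_lv in (("major_class", 8), ("chemovar", 7)):
        run = classify(s, level, n_lv, k=10, frac=0.67, seed=SEED,
                       steps=MODEL_PPT)
        run.metrics.to_csv(OUT / f"metrics_{level}.csv", index=False)
        run.rmse.to_csv(OUT / f"rmse_{level}.csv")
        run.band_vectors.to_csv(OUT / f"band_vectors_{level}.csv",
                                index_label="wavelength_nm")
        met = run.metrics
        cv = met[met.tier == "cross_validation"]
        pred = met[met.tier == "prediction"]
        print(f"[{level}] {n_lv} LVs | calibration n={len(run.calibration_idx)}, "
              f"prediction n={len(run.prediction_idx)}")
        print(f"  CV sensitivity:   {cv.sensitivity.min():.3f}-"
              f"{cv.sensitivity.max():.3f}")
        print(f"  pred sensitivity: {pred.sensitivity.min():.3f}-"
              f"{pred.sensitivity.max():.3f}")
        print(f"  max RMSECV/RMSEC: {run.rmse['RMSECV/RMSEC'].max():.3f}  "
              f"max RMSEP/RMSECV: {run.rmse['RMSEP/RMSECV'].max():.3f}")
        print(f"  explained Y variance (first two LVs): "
              f"{run.model.explained_y_variance[:2].sum():.1f}%")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    sys.exit(main())
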