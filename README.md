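# aquaspec

Aquaphotomics analysis of near-infrared spectra of wet (fresh) *Cannabis
sativa* inflorescence.

Freshly harvested cannabis flower is ~75-80% water, and the water bands that
dominate its NIR spectrum are usually treated as a nuisance.  Aquaphotomics
inverts that view: the water matrix acts as a "molecular mirror" of the
dissolved metabolites, and the absorbance pattern across twelve
characteristic water bands in the OH first overtone (1300-1600 nm) — the
Water Matrix Coordinates, C1-C12 — becomes the analytical signal.  This
package implements that workflow for researchers in NIR chemometrics and
cannabis phenotyping:

* **spectral_core** — wide-CSV I/O, replicate averaging, cropping to the OH
  first overtone, group mean/sd spectra;
* **preprocessing** — Savitzky-Golay smoothing/derivatives, MSC, SNV,
  detrend, mean centering, and leak-free calibration/apply pipelines;
* **plsda** — PLS2 discriminant analysis (SIMPLS), stratified 67/33
  calibration/prediction split, venetian-blinds cross-validation,
  per-class sensitivity/specificity/accuracy, RMSEC/RMSECV/RMSEP;
* **band_detection** — activated-water-band discovery from preprocessed
  spectra and PLS-DA loadings/regression vectors, WAMAC assignment,
  consistency tally;
* **aquagram_analysis** — aquagram values A'λ = (Aλ − μλ)/σλ per group,
  PCA, WAMAC and composition Pearson correlations, per-WAMAC ANOVA;
* **synthetic_data** — a seeded generator of the 7-chemovar, 187-sample
  study design with known ground truth, so the whole pipeline is testable
  without any proprietary data.

The model at the core: spectra X (n × p, log 1/R) are regressed onto class
indicators Y by PLS2; the aquagram standardizes the MSC-corrected
absorbance at each WAMAC over all samples, A'λ = (Aλ − μλ)/σλ, and reports
the mean per group — a relative water spectral pattern whose sample-weighted
group mean is zero at every band.

## Worked example

```python
import aquaspec as aq

# the default seven-chemovar study design (187 samples x 4 scans)
cfg = aq.default_cannabis_config(seed=0)
spectra, composition, truth = aq.simulate_spectraset(cfg)
s = aq.crop_wavelengths(aq.average_replicates(spectra), 1300, 1600)

# PLS-DA of the three major classes: MSC + smoothing, 8 LVs, 10-fold
# venetian blinds, stratified 67/33 split
run = aq.classify(s, "major_class", n_lv=8, k=10, frac=0.67, seed=0,
                  steps=aq.MODEL_PPT)
print(run.metrics[run.metrics.tier == "prediction"][["class", "sensitivity"]])
print(run.rmse["RMSECV/RMSEC"].round(3))

# chemovar aquagram over the 12 WAMACS
a = aq.compute_aquagram(s, "chemovar")
print(a.values["C5"].round(2).sort_values(ascending=False))
```

which prints

```
       class  sensitivity
6  high_CBDA          1.0
7  high_THCA          1.0
8     hybrid          1.0
class
high_CBDA    1.080
high_THCA    1.084
hybrid       1.081
Name: RMSECV/RMSEC, dtype: float64
621-17    1.84
Erez      0.31
240       0.28
156       0.12
45-3      0.06
505      -0.30
Gen12    -1.75
Name: C5, dtype: float64
```

Every major class is predicted perfectly on the held-out 33% (sensitivity
1.0), the RMSECV/RMSEC ratios sit near 1.08 (≤ 1.1 indicates negligible
over-fitting at this design size), and the C5 (free water, 1412 nm)
aquagram is highest for the 621-17 chemovar and lowest for the hybrid
Gen12 — the water-structure fingerprint planted in the generator.

## Analysis scripts

The numbered drivers under `analysis/` run the study end-to-end and write
plot-ready tables under `results/`:

```bash
python analysis/01_simulate_dataset.py      # 187-sample design -> results/data/
python analysis/02_explore_spectra.py       # group means/sd, 2nd-derivative band reading
python analysis/03_classify_plsda.py        # Table-style metrics + RMSE profiles
python analysis/04_detect_bands.py          # band tally across all sources
python analysis/05_aquagrams.py             # aquagrams, PCA, correlations, ANOVA
python analysis/06_composition_correlation.py  # WAMAC x analyte correlations
```

A `aquaspec` console script exposes the same stages
(`simulate`, `preprocess`, `classify`, `aquagram`, `correlate`, `run-all`).

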