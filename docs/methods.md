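# Methods

`aquaspec` implements an aquaphotomics workflow for near-infrared spectra of
wet *Cannabis sativa* inflorescence: spectral preprocessing, PLS-DA
classification of chemovars and major cannabinoid classes, discovery of
activated water bands, aquagram (water spectral pattern) computation over the
twelve Water Matrix Coordinates (WAMACS), and correlation of aquagram values
with chemical composition.  Because no public spectra of this kind are
available, the package ships a seeded generator that emulates the study
design end-to-end; every stage is validated against that generator's known
ground truth.

## Data model and conventions

Spectra are absorbance-like log(1/R) values on a strictly ascending
wavelength grid in nm.  All analysis is restricted to the first overtone of
the OH stretching band, the closed interval [1300, 1600] nm.  Band positions
quoted in the aquaphotomics literature need not sit on an instrument grid, so
all wavelength matching is nearest-grid-point with a stated tolerance
(default 6 nm).  Savitzky-Golay filters assume uniform spacing;
`resample_uniform` linearly interpolates onto a uniform grid (default 2 nm
step) when needed.

Each physical sample is measured as four scans from different directions.
Models and aquagrams operate on replicate-averaged spectra by default
(configurable): averaging four scans suppresses scan-level noise by half and
matches the convention of reporting one row per sample.

## Preprocessing

The implemented pre-treatments are Savitzky-Golay smoothing and derivatives,
multiplicative scatter correction (MSC), standard normal variate (SNV),
polynomial detrend, row normalization, and column mean-centering.  Composition
is ordered and explicit; two pipelines are bundled:

* model pipeline: MSC, then smoothing (SG window 11, polyorder 2, deriv 0);
* exploration pipeline: 2nd derivative (SG window 15, polyorder 3), then
  MSC, then smoothing.

The exploration order — derivative before MSC — is unusual but implemented
as stated by the workflow it reproduces; the order is configuration, not
code.  "Smoothing" is SG with derivative order 0; the windows were chosen to
resolve bands ≥ 10 nm apart on a 2 nm grid and are configurable.  SG
derivatives are scaled by the grid step, so units are per nm^deriv.  Edge
handling fits the edge-window polynomial and evaluates it (scipy's
``interp`` mode) rather than reflecting data, which would fabricate
absorbances beyond the measured range.

MSC fits each spectrum as x = a + b·ref by least squares and returns
(x − a)/b together with the fitted (a, b) for audit.  Statistics that depend
on the data — the MSC reference spectrum and column means — are fitted on
calibration data only and replayed on held-out data (`Pipeline.fit_transform`
vs `Pipeline.transform`); a checksum of the fitted state guards against
leakage in tests.

## PLS-DA

Class labels are indicator-coded (columns in sorted label order) and fitted
with PLS2 regression using the SIMPLS deflation, which is deterministic and
has no random initialization.  Samples are split 67/33 into calibration and
prediction groups, stratified per chemovar with a seeded RNG (round(0.67·n)
per chemovar; the 187-sample design yields 125/62).  Cross-validation uses
the venetian-blinds scheme: sample i of the calibration set (dataset order)
belongs to fold i mod k, k = 10 by default.  Fold assignment is therefore
deliberately order-dependent, which is documented and tested.  Preprocessing
statistics are re-fitted inside every fold on the training portion only.

Class assignment is argmax over predicted indicator scores; exact ties go to
the first class in sorted order and are logged.  Latent-variable counts are
fixed by configuration (8 for the three major classes, 7 for the seven
chemovars) — no automatic selection is attempted.  Metrics are per class,
one-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, reported for the calibration, cross-validation and prediction
tiers, alongside RMSEC/RMSECV/RMSEP on the indicator scale and the ratios
RMSECV/RMSEC and RMSEP/RMSECV.

### Finite-sample behaviour of the over-fitting ratio

On the default synthetic design the per-class RMSECV/RMSEC ratio
concentrates near 1.09 with a seed-to-seed standard deviation of about 0.01.
This is the expected finite-sample optimism of a fixed 8-LV model fitted to
125 samples: roughly sqrt((1 + k/113)/(1 − k/125)) for k ≈ 8 fitted
directions, i.e. a floor near 1.07 before the maximum over three classes is
taken.  Ratios comfortably below 1.1 therefore indicate a well-specified
model at this design size, but individual seeds can land slightly above 1.1
without implying meaningful over-fitting.  Seven chemovar clusters bound the
linearly informative rank at six, so at least two of the eight LVs always
absorb noise; this is a property of the mandated design (n = 125, 8 LVs,
10 splits), not of the implementation.

## Band detection

Activated water bands are read from two kinds of wavelength-indexed vectors:
second-derivative-preprocessed group mean spectra (where absorbance bands
appear as sign-inverted dips) and the PLS-DA LV loadings and per-class
regression vectors.  Local extrema are found with a prominence threshold
(default 10% of max |v|); extrema whose absolute value falls below a
magnitude floor (default the same 10%) are discarded, so the near-zero
saddle between two strong bands does not count as a hit.  Hits are assigned
to a WAMAC by range membership if ranges are declared, else to the nearest
canonical wavelength within tolerance, else left unassigned.  A consistency
tally counts distinct sources per WAMAC; "consistently activated" defaults
to a majority of sources (ceil(n/2)) because the qualitative notion it
formalizes is unquantified in the literature.

The registry stores one canonical aquagram wavelength per coordinate
(C1-C12: 1342, 1364, 1374, 1384, 1412, 1426, 1440, 1452, 1462, 1476, 1488,
1512 nm) with free-text physical annotations; reported positions for the
same coordinate vary between analyses (e.g. C5 near 1404-1412 nm), which the
matching tolerance absorbs.

## Aquagram

The aquagram value of group g at WAMAC λ is A'λ = (Aλ − μλ)/σλ, computed
after MSC against the dataset mean.  Taken literally, a per-group μλ and σλ
("all spectra assigned for a specific group") makes every group value
identically zero; that reading is retained as `per_group_literal` mode and
emits a prominent warning.  The default `classic_dataset` mode uses
dataset-wide μλ and σλ (population sd) and reports each group's mean
standardized value, which is the classic relative aquagram: its values
depend on the composition of the dataset, and the sample-size-weighted mean
over groups is exactly zero at every WAMAC.  Each WAMAC is read at the
single nearest grid wavelength by default; window averaging is available but
off (width 0), since point wavelengths are the quoted convention.

Downstream statistics: PCA of the column-centred group × WAMAC matrix by
SVD (scores, orthonormal loadings, explained variance); Pearson correlations
between WAMACS across groups and between WAMACS and per-chemovar analyte
concentrations (two-sided p from the t distribution, n − 2 df;
zero-variance columns reported as missing, never as 0); and per-WAMAC
one-way fixed-effects ANOVA on the sample-level standardized values.  The
ANOVA is one-way deliberately: the workflow it follows names a two-way
design without naming the second factor, and guessing one would manufacture
structure.  p-values are unadjusted by default with Benjamini-Hochberg
adjustment available, since only α = 0.05 is specified and a multiplicity
rule is not.

## Synthetic data generator

The generator emulates the seven-chemovar study: 621-17, Erez, 505, 240
(high THCA), Gen12 (hybrid), 156 and 45-3 (high CBDA) with sample counts
21/30/25/25/30/26/30 (187 total), four scans per sample, on a 1300-1600 nm
grid at 2 nm.  For sample i of chemovar g, scan r:

    A(λ) = m_i · [b0 + b1·(λ−1300) + Σ_k α_ik · exp(−(λ−c_k)²/(2σ_k²))] + o_i + ε_ir(λ)

with twelve Gaussian bands at the WAMACS centres (width 7 nm),
multiplicative scatter m_i ~ N(1, 0.05), additive offset o_i ~ N(0, 0.02),
and per-scan noise (white sd 0.001 per wavelength plus a scalar scan offset
sd 0.001).  Per-sample band amplitudes are

    α_ik = a_gk + (factor scores)·F + β_k·z_i(analyte) + iid jitter,

where F holds two collective water-state factors (solvation-shell strength;
free-versus-strongly-bound balance) with score sd 0.015, and the iid
per-band jitter sd is 0.001.  Concentrating within-sample variation in a
few collective modes mirrors how real wet-tissue spectra vary (hydration
state, not independent band-by-band wiggle) and keeps the fixed-LV models
well specified.

The chemovar amplitude patterns a_g are a shared wet-plant water profile
(peaking near 1452 nm, where the raw-spectrum standard deviation is
largest) plus per-chemovar deltas that qualitatively mimic the reported
orderings: the strongest free-water band (C5) in 621-17, elevated
solvation-shell bands (C2-C4) in 156, elevated strongly-bound water (C12)
in Erez/505/240/Gen12, and the weakest C3-C5 in the hybrid Gen12.  The
deltas are scaled so that every between-class contrast is at least 5× the
within-class amplitude noise along the separating direction (verified by a
test); they are qualitative mimics, not fitted values — no aquagram numbers
exist to fit.

Composition is a per-chemovar table of designed analyte means (THCA, CBDA,
CBGA, guaiol, α-pinene, β-myrcene in DW%, plus wet water content), with the
CBGA means ordered inversely to the C5 amplitudes and positively with C12,
and guaiol following C2-C4 — so the default dataset carries a realistic
composition-band association without explicit coupling (default β = 0).
Controlled coupling is provided by `planted_correlation_config`: given a
target chemovar-level correlation r between an analyte and one WAMAC
amplitude, it residualizes the base amplitude column against the
standardized analyte means z (removing the incidental correlation c·z) and
sets β = r·σ_e/sqrt(1 − r²), so the designed amplitudes mean + e + β·z
correlate exactly r with the analyte across chemovars.  Per-sample analyte
values add within-chemovar noise (5% of the across-chemovar sd), which
attenuates realized chemovar means only by order jitter/sqrt(n_g).

What the generator does **not** emulate: Lorentzian/Voigt band shapes,
wavelength-dependent scatter (only affine scatter is simulated, which MSC
removes exactly by construction), temperature sensitivity of the water
bands, instrument drift, and non-Gaussian biological outliers.  Passing
tests therefore demonstrate the correctness and statistical calibration of
the pipeline, not the field performance of NIR classification on real
inflorescence.

## Numerical choices and degenerate inputs

* MSC slopes below 1e-8 in absolute value raise an error naming the sample.
* SNV and aquagram computation raise on zero-variance rows/columns rather
  than emitting infinities; correlations with a constant column are missing
  (NaN), never 0.
* SIMPLS stops early with a warning when a deflation step drops below rank
  tolerance 1e-12; the effective LV count is recorded.
* Argmax ties in class assignment go to the first sorted class and are
  logged; a CV fold that loses a class entirely is recorded as a warning and
  metrics are still computed.
* The stratified split uses floor(frac·n + 0.5) per stratum, avoiding
  banker's rounding surprises.

## Problem sizes

The bundled analyses and tests run the full 187-sample design (151
wavelengths): one classification with 10-fold CV takes well under a second,
the 100-run planted-correlation recovery about half a minute, and the
1000-replicate ANOVA null calibration a few seconds, so the whole suite
completes in about a minute on one CPU.
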