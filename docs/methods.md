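# Methods

This note documents the models and numerical choices behind `nirselect`:
what each stage assumes, which tunables matter, what the synthetic data
generator does and does not emulate, and where the design was genuinely
open. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and I/O

Spectra are held as a samples × wavelengths absorbance matrix
(log 1/R) with a strictly ascending wavelength axis in nm or cm⁻¹ and an
optional reference concentration vector (mg/g). Descending axes — the
natural output order of wavenumber instruments — are reversed on load
together with the matrix columns, so selection indices always refer to the
ascending axis. The CSV dialect prints wavelengths at 6 significant
digits and data values at shortest round-trip precision; saving twice is
byte-identical, and load∘save is the numeric identity.

Replicate averaging is the arithmetic mean of the stored absorbance rows.
Whether replicates should be averaged before or after the
reflectance→absorbance transform is an instrument-protocol question the
library cannot decide; averaging operates on the representation as loaded,
and the reflectance conversion is an explicit load option.

## Preprocessing

All operators separate *fitting* (estimating statistics on the
calibration set) from *application*, so a fitted pipeline can be replayed
exactly on prediction spectra; SNV and Savitzky–Golay are per-row and
stateless. Standard deviations use the n−1 (sample) convention
throughout.

* Mean centering / autoscaling hit their column targets to 1e−10 on the
  fitted set by construction.
* MSC regresses each spectrum on the calibration-mean reference (the
  standard choice) and removes the fitted intercept and slope. On spectra
  that are exact affine distortions of the reference this inverts the
  distortion exactly.
* Savitzky–Golay uses `scipy.signal.savgol_filter` with `mode="interp"`:
  output width equals input width, with edge points evaluated from the
  polynomial fitted to the boundary window rather than truncated. This
  preserves the column geometry that selection indices refer to.
  Derivatives are scaled by the wavelength step (per-nm units); non-uniform
  axes are rejected for derivatives because a single step is undefined
  there. Defaults window = 11, polyorder = 2 are ordinary smoothing
  settings for ~1.5 nm-resolution FT-NIR grids.

## Kennard–Stone partitioning

Deterministic max–min selection on Euclidean distances: seed with the most
distant pair, then repeatedly add the sample whose minimum distance to the
selected set is largest, until the calibration set holds round(ratio·n)
samples (default ratio 0.75, i.e. the conventional 3:1 split). Ties break
toward the lowest index, which makes the algorithm permutation-equivariant
up to ties and exactly reproducible. Distances should be computed on the
preprocessed spectra used for modeling; the pipeline does this with a
provisional whole-set preprocessing pass used *only* for distances — the
statistics actually applied to the model inputs are then re-fit on the
calibration rows alone (see Leakage below).

## Monte Carlo outlier detection

Each iteration draws a uniform random train/test split (default train
fraction 0.75), fits a PLS model (internally mean-centered) on the train
part, and records the signed errors y−ŷ of the test samples. The default
iteration count is ⌈500/(1−train_fraction)⌉ so each sample is expected in
the test set about 500 times. After accumulation each sample has a MEAN
(systematic misfit) and SD (instability) of its errors.

Flagging is automatic rather than visual: a sample is an outlier when
|MEAN| > median(|MEAN|) + k·MAD(|MEAN|) or SD > median(SD) + k·MAD(SD),
with k = 3 and the normal-consistent MAD scaling (×1.4826). Two
properties of this rule matter for interpreting results:

* it is robust — the planted gross-error samples in the simulations are
  recovered essentially always and hold the top |MEAN| ranks; and
* it has a small but nonzero per-sample false-positive rate (order 1% for
  approximately normal error distributions), so the flagged set is
  expected to be a *superset* of the true outliers. Exact-set recovery is
  not a property any median+MAD threshold can deliver at k = 3; users who
  need conservative removal should inspect the diagnostics table (the CLI
  prints it) before deleting samples.

## PLS and cross-validation

PLS1 by the classical NIPALS recursion with deflation of both X and y;
the regression vector is b = W(P'W)⁻¹q with P'W upper-triangular. X and y
are centered inside `fit_pls` even if the pipeline already centered them
(centering is idempotent), which keeps every model self-contained inside
CV folds. If the residual X–y covariance vanishes before the requested
number of latent variables, fitting stops early with a warning.

Cross-validation refits the centering per training fold and evaluates all
component counts 1..max_lv from a single fit per fold (the per-h
regression vectors are triangular solves on the leading blocks).
Venetian-blind folds (every folds-th sample) are the deterministic
default; a seeded random scheme is provided. The chosen complexity is the
smallest LV count whose RMSECV is within 2% of the minimum — a parsimony
band that avoids buying noise components for negligible gain. A fixed LV
count can be supplied instead to reproduce externally specified settings
(published full-spectrum NIR models conventionally print LVs = 10).

## Ordered predictors selection

The informative vectors are computed on centered data. REG, VIP, WGHT,
SQR and NAS derive from a pilot NIPALS model with h components; COR, COV
and URXY are direct X–y statistics. Two definitions deserve comment
because the literature states them loosely:

* **SQR** is implemented as the per-variable explained fraction
  1 − ‖x_j − x̂_j‖²/‖x_j‖² of the h-component reconstruction X̂ = TP'.
* **NAS** is the per-column norm of the rank-1 y-correlated approximation
  X b b'/‖b‖², i.e. |b_j|·‖Xb‖/‖b‖² — the net-analyte-signal construction
  taken from the regression vector.

Both are isolated behind the vector-kind name so an alternative reading
can be swapped in without touching the search.

The prefix schedule evaluates sizes window, window+increment, …; the full
width is always appended as a final candidate, which guarantees the chosen
subset's RMSECV never exceeds the full-spectrum RMSECV under the same CV
scheme. Defaults scale with the problem: window = 10·h and
increment = p/50, both overridable. autoOPS evaluates the eight base
vectors plus the element-wise products of all min–max-normalized pairs
(28 combinations; triples are excluded to bound the search), breaking
ties toward fewer variables and then vector-kind name. feedOPS reruns
autoOPS on its own selection until the subset stops changing, the relative
RMSECV improvement falls below 1e−3, or 10 rounds elapse; subset size is
non-increasing across rounds by construction. iOPS cuts the axis into
contiguous intervals (the last may be short; intervals narrower than the
window are evaluated as a single candidate), selects within each, pools
the picks and reselects — all results reported in original coordinates.

## Successive projections algorithm

Chains are built on calibration-mean-centered columns; each step projects
every unselected column orthogonal to the span of the selected ones and
appends the largest residual (columns with residual norm below 1e−10 are
exhausted — linear combinations of selected columns are never picked
while independent columns remain). Candidate starts default to every
column (the historical "random start" made exhaustive and deterministic);
above 2000 columns the 200 most y-correlated columns are used. Prefixes
are scored by MLR RMSE on the validation set; RMSE differences below
1e−10·sd(y_val) count as ties so the smaller subset wins — without this
floor, exact fits on noiseless data would be ranked by floating-point
dust and the parsimony rule could never apply.

Scoring subsets on the prediction set follows the method's historical
definition and does let the validation data influence selection; the
pipeline documents this as its one exception to the leakage policy, and
`spa_select` can equally be fed an interior validation split by callers
who prefer strict separation.

## Evaluation

RPD uses the prediction-set reference standard deviation (n−1) over
RMSEP; RER uses the prediction-set reference range by default. Reports
round to 4 decimals for R²/RMSE and 2 for RPD/RER/SEP-SEC when formatted,
and serialize at 6 significant digits (lossless round trip at that
precision). RPD and RER are undefined at RMSEP = 0 and raise rather than
return infinities.

## Synthetic data generator

The generator produces Beer–Lambert mixtures X = C·S with optional
per-sample polynomial baseline drift (degree ≤ 2), per-sample
multiplicative gain, and iid Gaussian noise. The default scenario
emulates fresh plant tissue on a 1000-point, 1000–2500 nm grid with 260
samples and four components: a phenolic analyte (bands near 1440, 1700
and 2000 nm — O-H overtone and combination regions; concentration uniform
on 0.05–0.20 mg/g), a dominant water-like interferent (strong ~1920 nm
combination band, moisture varying a few percent around 1), and two broad
nuisance components overlapping the analyte bands. Additive noise
defaults to 0.001 absorbance units, a typical FT-NIR noise floor.
Distortions are off in the plain scenario and on in
`with_distortions()` — the end-to-end variant used by the workflow
demonstrations, since baseline and scatter are what the preprocessing and
selection stages exist to remove.

The ground-truth informative set is every grid index within ±2σ of an
analyte band center; it depends only on the scenario geometry, never on
the draw. *Coverage* of a selection is the fraction of truth indices
whose band region (center ± 2σ) contains at least one selected
wavelength — a handful of selected variables per band therefore covers
the band, which is the right notion for methods that deliberately return
few, minimally collinear wavelengths.

What the generator does **not** emulate: wavelength-correlated (pink)
noise, instrument response and resolution effects, nonlinear
detector/path-length behavior, and concentration correlations between
components. One consequence is worth stating plainly: on the *clean*
scenario (low-rank bilinear signal, iid noise) a full-spectrum PLS model
is statistically near-optimal, and variable selection can match but not
beat its prediction error. The advantage of selection that motivates
these methods on real spectra appears in the distorted scenario and grows
with structured, uninformative variation. Passing recovery tests here
demonstrates that the algorithms find the informative bands and preserve
predictive accuracy with far fewer variables — not that selection always
improves RMSEP on arbitrary data.

## Workflow and provenance

Stage order is fixed: outlier scan (on the full sample set, before
splitting) → preprocessing → Kennard–Stone split → selection chain → model
fit → evaluation. The outlier scan runs on spectra as loaded with PLS's
internal mean centering, i.e. effectively mean-centered inputs. Leakage
policy: prediction rows never contribute to preprocessing statistics,
outlier decisions, or OPS cross-validation; SPA's validation-set scoring
is the single documented exception. The manifest records the package
version, seed, full config, a SHA-256 config hash and one log line per
stage with input/output dimensions; identical config + seed reproduces
every artifact byte for byte (no timestamps enter any output).

## Problem sizes in the shipped checks

The test suite exercises module behavior on reduced scenarios (typically
80 samples × 200 wavelengths) and the end-to-end study at the full
260 × 1000 scale over 20 seeds with 5-fold CV, OPS increment 50 and
Monte Carlo scans of 300 iterations; `scripts/acceptance.py` runs 5 seeds
of each study. These sizes are the package's own choice of a
desk-reproducible experiment; all of them are config fields, and nothing
in the implementation depends on them.

## Known limitations

* PLS1 only (single response); no PLS2, kernel or robust variants.
* OPS combination vectors are limited to pairwise products.
* SPA has no post-selection parsimony elimination (F-test style).
* The outlier rule's false-positive rate means automated removal is
  slightly conservative-biased; inspect diagnostics before deleting.
* JCAMP-DX/SPC instrument formats are out of scope; convert to the CSV
  dialect first.
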