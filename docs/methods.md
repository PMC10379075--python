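# Methods

`freshnir` implements the full chemometric calibration chain used to
predict meat-freshness indicators from near-infrared (NIR) spectra:
total volatile basic nitrogen (TVB-N, mg/100 g; the regulated spoilage
indicator with a 15 mg/100 g first-grade bound) and texture rebound
(resilience, unitless, from double-compression texture profile
analysis).  This note documents the models, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Pipeline

The chain runs in the order a storage study prescribes:

1. **Load or generate** a spectra matrix (samples × channels, absorbance)
   with its wavelength axis, plus a per-sample reference table.
2. **Preprocess** the whole set with one (or a chain) of: MSC, SNV,
   min-max normalization, Savitzky–Golay smoothing or its first/second
   derivative.
3. **Screen outliers** by Mahalanobis distance in PCA score space.
4. **Partition** calibration/prediction sets 7:3 (SPXY by default).
5. **Select wavelengths** on the calibration set (CARS, SPA or UVE).
6. **Fit** a PLS1 or RBF ε-SVR calibration and **evaluate** R²c/RMSEC,
   R²p/RMSEP, LOD and LOQ on the untouched prediction set.

Screening runs *before* the split, on the preprocessed full set, because
that is how removal counts per preprocessing method are defined in this
kind of study (the screen decides which samples exist at all before any
set is formed).  Consequently the threshold optimization sees all
reference values; the no-leakage guarantee applies to the post-split
stages — wavelength selection and model fitting never see prediction-set
targets, which is what the leakage audit in the test suite checks.

## Preprocessing

* **MSC** regresses each spectrum on a reference spectrum
  (`x ≈ a + b·ref`, least squares) and returns `(x − a)/b`.  The
  reference is the mean spectrum of the set the transform is *fitted*
  on, frozen, and reused for later sets; a constant spectrum (fitted
  `b = 0`) is passed through with a warning.  MSC corrects each spectrum
  only up to its own affine fit: applied to spectra distorted by
  per-sample multiplicative/additive scatter it reproduces the MSC of
  the clean spectra exactly, and reproduces the clean spectra themselves
  only when those are affine in the reference.
* **SNV** standardizes each spectrum to mean 0, sd 1 (n−1 denominator,
  consistent with the sample statistics used in the metrics).
* **Normalization** is per-spectrum min-max scaling to [0, 1]; a
  unit-vector alternative is available behind the same interface.
* **Savitzky–Golay** uses `scipy.signal.savgol_filter` with
  `mode="interp"` (edge windows refit the polynomial, so output length
  equals input length) and derivatives scaled by the wavelength step
  (per-nm units).  Defaults are window 11, polyorder 2.  The rebound
  preset overrides the window to 31: at the default 1 nm sampling the
  informative bands are 30–50 nm wide, and a second-derivative kernel
  much narrower than the feature scale amplifies channel noise without
  adding resolution (measured on the default synthetic study: prediction
  R²p ≈ 0.74 with window 11 versus ≈ 0.99 with window 31).
* Scatter correction (MSC/SNV) is a *data-dependent* per-spectrum
  normalization.  In the noiseless, scatter-free limit it slightly bends
  the otherwise exactly affine spectrum–indicator relation, so the
  noiseless-limit exactness properties are stated for the linear
  operators (identity, SG smoothing and derivatives).

## Outlier screening

Distances are computed in truncated PCA score space:
`D_i = sqrt((t_i − T̄) M⁻¹ (t_i − T̄)ᵀ)` with `T̄` the mean score vector
and `M` the (n−1) covariance of the scores.  The number of retained
components is the smallest explaining ≥ 99% of variance, capped at 10.
The removal threshold is `D_th = D_m + e·σ_d` (mean and sd of the
distances).  The weight `e` is chosen on a grid (0.5–5.0, step 0.25):
for each candidate the screen is applied and a PLS calibration is
5-fold cross-validated on the survivors; the `e` with minimum CV RMSE
wins, ties toward smaller `e`.  Grid points leaving fewer than
`2·max_LV` survivors are skipped.  Screening is single-pass — one
removal round, no iterative re-screening.  Larger `e` always removes
fewer samples (monotonicity is a tested invariant).

## Partitioning

* **Kennard–Stone** seeds the calibration set with the maximum-distance
  pair, then repeatedly adds the sample with the largest minimum
  distance to the current set.  Deterministic; all ties break to the
  lowest sample index (relevant for duplicated spectra).
* **SPXY** applies the same greedy rule to
  `d_xy = d_x/max d_x + d_y/max d_y`; a constant `y` degenerates to
  plain KS with a warning.
* The random split is seeded and uniform.  The default ratio is 0.7.
  Both greedy methods are verified index-for-index against brute-force
  reimplementations on random instances with n ≤ 10.

## Wavelength selection

* **CARS** (50 Monte-Carlo runs, 80% sample draws, 5-fold CV): each run
  fits PLS on a random sample subset, ranks variables by |regression
  coefficient|, enforces the exponentially decreasing retention schedule
  `r_i = a·exp(−k·i)` calibrated so `r_1 = 1` and `r_N = 2/p`, then
  resamples variables (p weighted draws with replacement); the
  iteration whose survivors minimize CV RMSE wins.  The PLS dimension is
  fixed once at the CV optimum of the full calibration set: over-sized
  models produce noisy coefficient rankings and measurably degrade both
  band recovery and downstream error.  The post-schedule retained count
  is non-increasing by construction.
* **SPA** grows projection chains from the highest-norm centered
  columns (10 starts by default): each step adds the unselected column
  with the largest norm after projection onto the orthogonal complement
  of the selected ones, so selected columns are linearly independent by
  construction.  Chain prefixes are scored by ordinary-least-squares
  RMSE on a deterministic internal Kennard–Stone validation split
  (ratio 0.75); the best prefix wins, ties toward fewer variables.
* **UVE** appends one uniform noise column per real channel (amplitude
  `1e-10 × mean|X|` — large enough to register in the fit, too small to
  perturb it; the reliability statistic is scale-free), runs
  leave-one-out PLS collecting coefficient vectors, scores every column
  by `c_j = mean(b_j)/sd(b_j)`, and keeps real channels with `|c_j|`
  above the largest noise-column `|c|`.  Noise columns with degenerate
  (constant) coefficients are excluded from the cutoff with a warning.
  The PLS dimension defaults to the CV optimum on the real channels,
  for the same stability reason as in CARS.  UVE typically retains wide
  swaths around informative regions — a rough selection — and may
  retain nothing when `y` carries no spectral information.

### When selection can and cannot help

On data whose informative bands are broad, a full-spectrum PLS model is
already near-optimal: every additional band channel averages down
channel noise, and PLS is insensitive to the uninformative remainder.
We measured that even an oracle subset of the truly informative
channels only ties full-spectrum PLS there, so no selector can be
expected to *improve* prediction.  Selection pays off in the
sparse-information regime — few informative channels, material channel
noise — which is what the `sparse_config()` benchmark encodes (narrow
3-channel bands, higher noise); CARS beats the full spectrum there.
The practical benefit of selection on broad-band data is model economy
(tens of channels instead of 1921, enabling cheap filter instruments),
not accuracy.

## Calibration and metrics

PLS1 is scikit-learn's NIPALS implementation (no scaling; centering
statistics from the training set only); the LV count is chosen by
minimum 5-fold CV RMSE over 1..10, ties toward fewer components —
10 matches the largest component count such studies report.  SVR is an
RBF ε-SVR on channel-standardized inputs, with (C, γ, ε) chosen by CV
over C ∈ {0.1, 1, 10, 100}, γ ∈ (1/p)·{0.1, 1, 10} on the standardized
matrix, ε ∈ {0.01, 0.1}.

Metrics: `R² = 1 − Σ(f−y)²/Σ(ȳ−y)²` and `RMSE = sqrt(mean (f−y)²)` on
calibration (R²c, RMSEC) and prediction (R²p, RMSEP) sets.  LOD and LOQ
use the calibration-curve convention `3.3·s_res/slope` and
`10·s_res/slope` (training-residual sd over the slope of the
predicted-vs-reference training line), so LOQ/LOD = 10/3.3 exactly.
The two indicators are modeled independently (PLS1 twice), never as a
joint response.

## Synthetic data generator

The generator emulates a chilled-meat storage study: 6 groups — two
temperatures (4/10 °C) × three atmospheres (70/20 and 50/40 O₂/CO₂
modified-atmosphere mixes, plain air) — 10 storage days, 3 samples per
group and day (180 samples), 5 scans per sample on a 700–2620 nm axis
at 1 nm (1921 channels).  The axis is the minimal one consistent with
1921 points covering the working range of such instruments.

Reference trajectories: TVB-N rises logistically from ≈8 to
≈25 mg/100 g (faster at 10 °C and in plain air; crosses the 15 mg/100 g
bound within the window for every group); rebound declines slowly for
days 0–5 and faster afterwards (two-phase decline).  Small biological
jitter (sd 0.25 mg/100 g and 0.006 respectively) is added per sample.

Spectra: eight Gaussian absorption bands whose latent concentrations
are affine in the normalized indicators plus band-specific nuisance
terms, on a smooth background; each scan is distorted by multiplicative
scatter (sd 0.05), additive offset (sd 0.02), a linear baseline tilt
and iid channel noise (sd 0.005); the five scans are averaged into one
spectrum per sample — reference values are per sample, and averaging
before any split prevents replicate leakage.  All randomness flows from
one seed; generation is bit-reproducible.

What the generator does *not* emulate: physically assigned NIR band
positions for meat constituents (overtones/combination bands of water,
protein, fat), wavelength-dependent noise, instrument drift,
nonlinear detector response, or sample-temperature effects.  Passing
tests therefore demonstrate that the chain's algorithms behave as
specified on data with the assumed statistical structure — not that the
preset pipelines would reach the same accuracy on spectra from a real
instrument.

Benchmark configurations frozen for testing: `recovery_config()`
(10 nm axis, 193 channels, eight well-separated bands with
equal-magnitude alternating-sign loadings — comparably informative for
either indicator — at band-center SNR ≈ 20; a ±3-channel neighborhood
spans a band, making recovery counting meaningful) and
`sparse_config()` (same axis, 10 nm-wide bands, heavier noise; the
regime where selection beats the full spectrum).  Outlier-screening
benchmarks use a 400-channel axis; the two preset pipelines are always
exercised at the full 180 × 1921 scale.

## Known limitations

* The generator's spectrum–indicator relation is affine by
  construction, so linear models are close to the Bayes optimum; SVR's
  advantage on real TVB-N data (nonlinear spoilage chemistry) cannot
  show up here.
* LOD/LOQ values are convention-dependent; only their ratio is
  invariant.
* UVE's leave-one-out loop is O(n) PLS fits and is the slowest stage at
  full scale (~2 s at n≈120, p≈3800 augmented); a Monte-Carlo CV
  variant would be preferable for n in the thousands.
* Screening before splitting means the threshold search uses all
  reference values; if strict train-only screening is needed, run the
  stages manually on a pre-split calibration set.
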