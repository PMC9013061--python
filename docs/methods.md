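# Methods

This note documents the statistical model behind `msirecal`, the defaults
and the reasoning behind the open design choices, what the synthetic data
generator does and does not emulate, and the known limitations.

## Model and assumptions

The central assumption is that mass drift is driven by slowly varying
instrumental conditions, so the observed m/z of a fixed ion is a *smooth
function of acquisition time*. Pixel order stands in for time: imzML
storage order is taken as acquisition order (an explicit order vector can be
passed to `read_imzml` when that is known to be false, e.g. for serpentine
rasters re-sorted by a converter).

Given that assumption, a global reference ion detected in most on-tissue
pixels traces a smooth "drift track" in the (pixel order, observed m/z)
plane, and three consequences are exploited:

* the track can be separated from interferent peaks by density: the 2D KDE
  ridge follows the locally densest signal, and a candidate whose matched
  peaks scatter across several tracks shows a large residual dispersion and
  is rejected;
* the track can be *interpolated*: a penalized-spline GAM predicts the
  reference's observed m/z in pixels where it was not detected, so the
  per-pixel calibration always has a full complement of references;
* per pixel, calibration reduces to a small regression of theoretical on
  predicted-observed masses, in the coordinate system natural to the
  analyzer (linear in m/z for orbital traps; polynomial in √(m/z) for
  time-of-flight, whose flight time is proportional to √(m/z)).

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| search window W | 20 (Orbitrap) / 100 (TOF) | ppm | candidate match window, λ = W·M·10⁻⁶ |
| coverage threshold | 0.75 | fraction | minimum ROI fraction with ≥1 match / ≥1 inlier |
| dispersion threshold | 10 | ppm | maximum 2·mad(r)/S(p)·10⁶ over inliers |
| KDE grid G | 1024 | — | density resolution per axis |
| KDE bandwidth | 2.576·σ·N^(−1/5) | scaled units | σ = pooled per-axis SD of the min/max-scaled points |
| ridge-spline s grid | 30 values, 10⁻⁵…10⁻¹ | — | `UnivariateSpline` smoothing, 5-fold CV |
| GAM terms J | 20 | — | cubic B-spline basis size over pixel order |
| GAM penalty grid | 11 values, 10⁻³…10³ | — | second-difference penalty, GCV-selected |
| common-error band | 2.5 (Orbitrap) / 10 (TOF) | ppm | half-width around the per-pixel error mode |
| TOF max degree D | 5 | — | BIC-selected √m polynomial degree |
| component min size | 50 | pixels | 8-connected ROI cleanup |
| evaluation window | 2.5 | ppm | test-mass consistency band around the error mode |
| bootstrap B | 10,000 | — | pixel resampling repetitions |

The coverage and dispersion thresholds, grids and basis sizes are the
method's standard operating point; all are exposed through
`PipelineConfig`.

## Numerical choices

**KDE.** The kernel is the separable product triangular kernel
(1−|u|)(1−|v|) on the axes scaled to [0, 1]; a product form (rather than a
radial one) makes the grid convolution separable and the normalization
elementary, and at the bandwidths involved the two are practically
indistinguishable. Points are linearly binned onto the G×G grid and
convolved with the sampled kernel by zero-padded FFT, so there is no
periodic wrap-around at the edges and the result equals the exact kernel
double sum over the binned weights (verified to < 10⁻⁶ against a
brute-force double sum). Linear binning error against the exact off-grid
point sum is bounded in tests at < 2% of the peak density — far below the
ridge tracer's grid quantization. Column-argmax ties take the smallest m/z
index; all-zero columns produce no ridge point.

**Ridge spline.** `scipy`'s `UnivariateSpline` with the smoothing factor
chosen by 5-fold cross-validation over 30 log-spaced values in
[10⁻⁵, 0.1]; folds are assigned by a seeded random permutation (random
rather than pixel-blocked folds — the ridge points are one-per-column and
nearly noise-free, so fold geometry has little leverage).

**Outlier rule.** Residuals are measured to the spline, r_i = |M#_i −
S(p_i)|, and the robust scale is taken *about the spline*: mad(r) =
median(r)/Φ⁻¹(3/4) ≈ 1.4826·median(r). Under Gaussian noise the cut
r_i ≥ 2·mad(r) then flags ≈ 4.6% of points — a mild single-pass sweep. (A
MAD taken about the median of the absolute residuals would flag ≈ 27% of
clean Gaussian points and starve the 75%-coverage gate; with the dispersion
also defined through 2·mad, the 10 ppm acceptance threshold then reads "2
robust standard deviations of the cleaned track must stay within 10 ppm",
matching the intent of a noise-scattering bound.) When mad = 0 only points
with r above the common (median) residual are flagged, so perfect tracks
lose nothing. The dispersion is computed on the inlier residuals: acceptance
should reflect the track that will actually be fitted.

**GAM.** The trend is a clamped cubic B-spline basis of J = 20 functions on
the full ROI pixel-order range with a second-order difference penalty on
the coefficients (the basis spans constants, so the intercept is implicit;
the response is centered for conditioning). For each penalty λ the ridge
system is solved directly (20×20) and GCV = n·RSS/(n − edf)² selected. With
coverage ≥ 75% spread over the acquisition, every basis function has
support; the penalty regularizes any locally thin stretch. Predictions are
clamped to the knot range (constant extrapolation at the acquisition ends).

**Per-pixel filter and fits.** The common-error mode is the argmax of a 1D
triangular-kernel KDE over the per-pixel reference errors (same bandwidth
rule; ties resolve to the lower ppm mode via first-argmax on an ascending
grid). If fewer than two references survive the band, the unfiltered set is
used with a warning — a pixel must still be recalibrated. The TOF BIC is
the Gaussian form n·ln(RSS/n) + (D+1)·ln(n); RSS is floored at the
machine-precision level of the response so that exactly interpolating fits
are ranked purely by the complexity penalty (degree 1 wins on exactly
linear data). Degrees whose design matrix is rank-deficient, or that would
leave fewer than 2 residual degrees of freedom, are skipped. A TOF
prediction landing at a negative √-domain value leaves that peak
uncorrected and flagged.

**Degenerate inputs.** All-equal intensities yield a warned-through kneedle
threshold; zero-variance point sets floor the KDE bandwidth at machine
epsilon; a degenerate per-pixel design (all predicted masses equal) leaves
the pixel uncorrected and logged; off-ROI pixels always pass through
unchanged.

## Evaluation statistic

Δ̃ is the median over pixels of the per-pixel *median of paired
differences* |err_before| − |err_after| over the matched test masses. The
phrase "median difference between the absolute mass errors" is ambiguous
between this and a per-pixel difference of medians; the paired-difference
reading is used because the bootstrap then resamples a single per-pixel
quantity. The bootstrap p-value is twice the fraction of pixel-resampled
medians whose sign contradicts Δ̃, clipped to [2/B, 1]; under a simulated
null its rejection rate at α = 0.05 is calibrated to 5% ± 2% in the test
suite. BH adjustment is the standard step-up (via `statsmodels`).

## Synthetic data generator

`simulate_dataset` emulates exactly the features the method exploits or
must survive: a smooth pixel-order drift field (mass-independent ppm sine
for Orbitrap-like data; a ppm field linear in √m — i.e. a quadratic
√-domain drift map, the TOF model class — normalized so the configured
amplitude is the maximum planted drift); Bernoulli per-pixel detection;
multiplicative ppm-scale Gaussian measurement noise; decoy interferents at
fixed ppm offsets with configurable (e.g. complementary) spatial masks;
uniform chemical-noise background peaks; log-normal intensities; off-sample
pixels with background only. Ground truth records, per pixel and ion, the
drifted mass *before* noise, the planted (noisy) mass and its position in
the spectrum.

Default study conditions: 50×40 grid (2,000 pixels, all on-sample), 20
reference and 20 held-out test ions over 255–900 Th, one sine period over
the acquisition, 5 ppm amplitude / 0.5 ppm noise / 90% detection for the
Orbitrap condition, and 60 ppm amplitude / 3 ppm noise for the TOF
condition — ppm scales matching the drift magnitudes the two analyzer
classes exhibit in practice. These sizes keep a full pipeline run in
seconds while leaving every gate (coverage, dispersion, GCV, BIC)
non-trivially exercised.

What it does **not** emulate: profile peak shapes, isotope envelopes,
intensity-dependent mass error, spatially structured chemical noise, or
detector saturation. Passing tests therefore demonstrate correct recovery
of smooth pixel-order drift under realistic noise and interference — not
robustness to every artifact of real acquisitions.

Scoring separates the *systematic* residual drift (the fitted calibration
evaluated at the noise-free drifted mass) from the total error read back
from the spectrum, which includes the irreducible per-peak measurement
noise; the systematic component is the quantity the recalibration actually
controls.

## Known limitations

* Calibration models extrapolate as fitted polynomials outside the
  reference-covered m/z range; per-pixel reports record that range, and
  errors at masses far outside it can be large (visible in the 95th
  percentile of the TOF condition). References spanning the acquisition
  range are essential.
* For TOF data with strongly mass-dependent drift, the per-pixel
  common-error band (a single mode ± band) retains a mass-local subset of
  references at the drift extremes, which is the dominant contribution to
  the residual error there.
* Only smooth time-dependence is modeled; abrupt condition changes
  (source cleaning, pauses) violate the GAM assumption.
* Only ROI pixels are recalibrated; off-sample pixels pass through, so
  off-tissue background signal keeps its drift.
* Singly charged adducts only; no isotope-pattern or in-source-fragment
  awareness.
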