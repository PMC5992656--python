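# Methods

## The measurement problem

A protein tagged with a fluorescent label may be partly associated with the
plasma membrane (PM) and partly dissolved in the cytoplasm (CP). At confocal
resolution the membrane is far thinner than the point spread function (PSF),
so even a strongly membrane-bound protein appears as a blurred rim whose
apparent intensity mixes with the adjacent cytoplasmic signal. `memfrac`
quantifies the membrane-associated component by unmixing intensity profiles
drawn perpendicular to the membrane in three simultaneously imaged channels:

- a **PM marker** (e.g. a lipidated Lck-tagged CFP) that labels the membrane
  but also retains a cytoplasmic pool,
- a **CP marker** (a freely diffusing RFP) that labels only the cytoplasm,
- the **protein of interest (POI)**, a YFP fusion.

## Pipeline

1. **Preprocessing** (`imaging_io`). An 8-frame time series per channel is
   averaged; channels are registered by a translation-only iterative
   Lucas-Kanade estimate (Gauss-Newton on the global-translation warp,
   seeded by an integer FFT cross-correlation so shifts up to the 20 px
   sanity bound converge); a scalar background per channel is subtracted
   (mean of a user ROI, else the 5th percentile of the frame-averaged
   image, which is robust when most of the field is extracellular).
   Negative values after subtraction are retained so the later least
   squares stays unbiased.
2. **Line scans** (`profiles.line_scan`). Along each user-drawn line
   (default 10 px wide, ~6-10 um long, perpendicular to the membrane) the
   image is sampled by bilinear interpolation and averaged across the
   width. The end-to-end pipeline samples at a half-pixel axial step so
   that the later regridding onto the common axis adds negligible extra
   broadening (see *Sampling transfer* below); `line_scan` itself defaults
   to a 1 px step.
3. **Alignment** (`profiles.align_and_average`). Each line is centered on
   its PM-marker peak (3-sample moving average, most prominent peak,
   parabolic subpixel refinement; ties break toward the line midpoint) and
   oriented with the cytoplasm — the side with the larger mean CP-marker
   intensity over |x| in [1, 2.5] um — at negative positions. All lines
   are linearly regridded onto a common axis ([-3.5, 3.5] um, one pixel
   spacing) and averaged per channel.
4. **Normalization** (`profiles.normalize_profiles`). Residual
   extracellular background (mean over x > 2 um) is subtracted per
   channel; each channel is then scaled so its cytoplasm-window mean
   (x in [-2.5, -1.5] um) is 1.
5. **Basis correction** (`profiles.correct_pm_marker`). Because the PM
   marker also has a cytoplasmic pool, the pure-membrane basis is
   f_corr = f_CFP - f_RFP.
6. **Unmixing** (`profiles.unmix_profile`). Non-negative least squares on
   x in [-2.25, 2.25] um: f_YFP = a_CP f_RFP + a_PM f_corr. The reported
   **PM peak** is max(a_PM f_corr) x 100, in percent of the cytoplasmic
   level. For two regressors the NNLS solution has a closed form
   (unconstrained solve, else the better of the two boundary solutions),
   which the bootstrap uses vectorized; the public path uses
   `scipy.optimize.nnls` and both are tested against an exhaustive grid
   search.
7. **Realignment** (`profiles.realign_on_pm`). The axis is recentered once
   on the unmixed PM-component peak and the averaging/normalization/
   unmixing is repeated. Realignment regrids from the raw line scans with
   the accumulated shift, so interpolation passes do not compound. A POI
   with no detectable PM peak is left unchanged and flagged.
8. **Bootstrap** (`profiles.bootstrap_ci`). Lines are resampled with
   replacement (n = 1000); each replicate redoes averaging, normalization,
   basis correction and unmixing (alignment is computed once on the
   original set). The 95% CI is the point estimate +/- 1.96 x the
   bootstrap SD, per axis position for the component profiles and as a
   scalar for the PM peak; percentile intervals are available as an
   option. Resampling is per line; cell-level resampling can be had by
   passing one averaged triple per cell.

## Synthetic ground truth

`synthetic` renders a disk-shaped cell (default radius 6 um) with an
excluded nucleus (2 um) and the membrane as an infinitely thin circular
line source — real membranes are far below optical resolution. Per channel
it applies a cytoplasm density c (photons/um^2), a membrane density m
(photons/um), an isotropic Gaussian PSF (defaults: 0.18 um for the PM
marker and POI, 0.21 um for the CP marker, emulating the wider PSF of a
red channel), an optional inter-channel shift, an additive background
(10 counts/px) and Poisson noise over 8 frames. Densities default to
~98 counts/px in the cytoplasm, a PM-marker peak at 300% of its cytoplasm
level and a POI peak at 20%.

The source map is rendered at 5x supersampling, convolved with the PSF,
and **sampled at pixel centers**: a point-scanning confocal records the
convolved field at discrete scan positions rather than integrating a
detector aperture. For a locally planar membrane the noiseless profile is
closed-form: c Phi(-x/sigma) for the cytoplasm edge plus
m/(sqrt(2 pi) sigma) exp(-x^2/2 sigma^2) for the membrane, so the
ground-truth peak is

    expected_pm_peak = 100 * (m / (sqrt(2 pi) sigma)) / c   [percent].

The planar form agrees with a scan of the rendered image to <1% for
radius >= 20 sigma.

What the generator does **not** emulate: endomembrane compartments, 3-D
sectioning, membrane undulation, cell-to-cell variability, chromatic
aberration beyond pure translation, detector read noise. Passing tests
therefore demonstrate correctness of the estimator under its own model,
not robustness to those real-data effects.

## Sampling transfer (why recovery is ~94%, not 100%)

Bilinear interpolation of an image sampled with pixel pitch h attenuates a
Gaussian peak of width sigma by roughly h^2 E[f(1-f)] / (2 sigma^2), with
f the fractional sample position (E[f(1-f)] = 1/6 for uniformly
distributed offsets). At h = 0.14 um and sigma = 0.18 um this is ~5%, and
the regridding onto the common axis adds a little more. The measured
basis-peak transfer of the full pipeline on noiseless images is ~0.94,
**multiplicative and identical at every membrane fraction** (the
coefficient a_PM itself is recovered essentially exactly, because the POI
and the basis suffer the same transfer). The same attenuation is inherent
to any analysis of real images with these settings; consequently
validation compares noisy runs against the noiseless-pipeline value, and
tests assert the multiplicative-transfer property rather than unit
recovery of the ideal analytic peak.

## The negative-control residual

With a soluble POI the unconstrained membrane coefficient is slightly
*negative* (~-0.2% peak) when the CP-marker PSF is wider than the POI's —
the PSF-mismatch term in the residual is odd about the membrane and
couples only weakly (and with negative sign) into the even membrane
basis. The non-negativity constraint clamps it to zero, and with Poisson
noise the reported peaks are censored at zero, giving small positive
values on average (<1%). Larger residuals reported for real negative
controls likely include effects beyond PSF width mismatch (residual
misregistration, membrane undulation, spectral bleed-through).

## FCS model

`fcs` fits autocorrelation curves with the standard 3-D Gaussian
observation-volume model, a triplet term bounded to tau_T in [0, 50 us],
and two diffusing components; the shape factor s (axial/lateral, default
5) is fixed from calibration. Diffusion times are globally linked across
measurements as one joint bounded least-squares problem
(`scipy.optimize.least_squares`, trf), with tau_D1 < tau_D2 enforced by
fitting log10(tau_D1) and the log10 ratio. Fits are unweighted by default
(per-point SD weights optional). Standard errors come from the Jacobian;
a triplet time pinned at a bound is flagged. Conversion to diffusion
coefficients uses a same-day reference of known D (D = D_ref tau_ref /
tau_D, the beam waist cancels), and the mean coefficient is the plain
fraction-weighted average f1 D1 + (1-f1) D2. When the truth has a single
component the two-component fit is degenerate: f1 tends to 0 or 1 and the
unused time is unidentified; the fraction-weighted mean D remains stable.

## Ratiometric conventions

- FRET ratio: (I_YFP - beta I_CFP)/I_CFP with donor bleedthrough beta =
  0.55 by default; with a stimulus time set, traces are additionally
  normalized per cell to the pre-stimulus mean (raw traces retained).
- Nuclear/cytoplasmic ratio: mean over user-supplied disjoint masks on a
  background-subtracted image; no automatic segmentation.
- Fold change: transfected-cell values divided by the mean of
  untransfected controls in the same field of view.
- Notched summaries: type-7 quantiles; whiskers at the most extreme data
  within 1.5 IQR of the quartiles; notch = median +/- 1.58 IQR/sqrt(n).
  Note that this notch spans ~1.7 standard errors of the median, so its
  exact single-median coverage for normal data is 2 Phi(1.7) - 1 = 91%;
  the factor is a compromise intended for comparing two notched boxes by
  eye, not a strict per-group 95% interval.

## Problem sizes and numerics

Validation simulations use a 144 px field (20.2 um) with a 6 um cell and
20 radial lines per dataset, which keeps a full dataset (render +
pipeline + 1000 bootstrap replicates) at ~0.25 s; recovery and coverage
studies use 30-50 datasets per condition (500 for the CI-calibration
study). Degenerate cases are handled explicitly: all-line rejection when
no PM-marker peak is prominent enough (default prominence >= 5% of the
profile range), an error when the cytoplasm-window mean is non-positive,
an error when the two bases are collinear inside the fit window, and a
flagged no-op realignment for membrane-free proteins. Bootstrap
replicates with a degenerate normalization are dropped as NaN.

## Known limitations

- Translation-only registration; no rotation, scaling or chromatic
  correction.
- The membrane-fraction estimate carries the multiplicative sampling
  transfer described above (~0.94 at default settings); comparisons
  between constructs imaged identically are unaffected.
- The bootstrap treats lines as independent; lines drawn close together
  on one cell share structure that the CI does not model.
- The FCS module fits user-provided correlation curves; it does not
  correlate photon streams, and anomalous/2-D membrane diffusion models
  are out of scope.
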