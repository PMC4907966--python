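# Methods

## The problem

Potassium sorbate (PS) and sodium benzoate (SB) are the two most widely
used acidic-food antiseptics, and both have to be dosed accurately —
individually and in combination. Surface-enhanced Raman scattering (SERS)
makes their trace spectra measurable, but the two molecules' strongest
Raman bands overlap, so a single-peak intensity calibration cannot
separate them. `serspls` implements the multivariate route: partial least
squares regression (PLSR) of solution concentration on the spectral
channels inside each analyte's characteristic peak sections. Because the
latent variables of PLSR are extracted to maximize covariance with the
*target* concentration, signal from the co-solute that varies
independently of the target is relegated to directions the regression
coefficient ignores — that is the mechanism the mixture experiments here
probe.

## The calibration model

For a calibration set of n spectra restricted to the target analyte's
windows, let X (n × m) hold the spectra and y (mg/L) the concentrations.
After mean-centering (X_c = X − x̄, y_c = y − ȳ; centering only, no
per-channel variance scaling), components k = 1…A are extracted by the
NIPALS recursion on the deflated pair (X_c, y_c):

    w_k = X_cᵀ y_c / ‖X_cᵀ y_c‖      t_k = X_c w_k
    p_k = X_cᵀ t_k / (t_kᵀ t_k)       q_k = y_cᵀ t_k / (t_kᵀ t_k)
    X_c ← X_c − t_k p_kᵀ              y_c ← y_c − q_k t_k

with the closed-form regression coefficient b = W (Pᵀ W)⁻¹ q and the
prediction rule ŷ(x) = (x − x̄)·b + ȳ. For a univariate response the first
weight is exactly the covariance-maximizing direction, which the tests
verify both analytically (w₁ ∝ X_cᵀ y_c) and against a Monte-Carlo oracle.
With A equal to the rank of X_c the training predictions coincide with
the minimum-norm least-squares fit; with fewer components PLSR is the
regularized interpolant between the covariance direction and that limit.

Numerical choices: all linear algebra in double precision; Pᵀ W is solved
directly and falls back to a pseudo-inverse with relative cutoff 1e-10 if
singular; deflation stops early (with a diagnostics flag, never an error)
when the residual covariance ‖X_rᵀ y_r‖ falls below 1e-12 of the product
of the current deflated norms — judged against the *current* magnitudes
rather than the initial ones so that wide matrices deflate to full rank.
Predictions are never clipped at zero, so blank samples may legitimately
come out slightly negative.

The number of components is chosen by leave-one-sample-out
cross-validation, capped at min(n − 2, 10). Curve values within 1e-9 of
the response scale of the minimum count as ties and the smallest A wins,
so noise-free rank-limited data selects the true rank instead of a
numerically jittered larger count.

R² is reported as the squared Pearson correlation between predicted and
actual concentrations — the R² of the straight line through the
predicted-vs-actual scatter, symmetric and affine-invariant — rather than
1 − SS_res/SS_tot. The published single-analyte figure pairs are only
mutually consistent under the correlation reading, so that is the form
the package standardizes on; the SS form would additionally penalize bias,
which RMSE already reports.

## The synthetic spectra

The study's measured spectra are not deposited, so the generator supplies
spectra with the statistical structure the analysis relies on:

* **Clean signal.** Each analyte is a fixed sum of Lorentzian bands
  (amplitude · hwhm² / ((ν − center)² + hwhm²)), the standard lineshape for
  Raman lines; pseudo-Voigt profiles were deliberately left out as adding
  nothing at the resolution simulated. Intensity scales linearly with
  concentration by default; a Langmuir saturation r(c) = c·c₅₀/(c₅₀ + c)
  is available but off by default.
* **Band libraries.** The real PS/SB peak positions are published only as
  shaded regions in a figure, so the default libraries are synthetic
  stand-ins — PS: (1640, 12, 1.0), (1380, 10, 0.6), (1140, 10, 0.4); SB:
  (1600, 10, 1.0), (1026, 8, 0.5), (1002, 6, 0.9) (center cm⁻¹, HWHM cm⁻¹,
  relative amplitude per mg/L) — chosen so that the strongest PS and SB
  bands fall inside each other's calibration windows, reproducing the
  overlap that makes the mixture problem interesting. They make no claim
  to match the real molecules' wavenumbers.
* **Site-to-site variability.** Replicate spectra taken at random substrate
  positions differ mainly in overall enhancement, modelled as one
  log-normal factor g ~ LogNormal(0, σ_mult) per spectrum (whole-substrate
  enhancement, not per-analyte; competitive-adsorption factors would be a
  config extension and are off). E[g] = exp(σ²/2), which a moment test
  checks empirically.
* **Channel noise and baseline.** Additive iid Gaussian noise whose s.d.
  is a fraction of the maximum clean intensity over the design being
  simulated (one absolute noise floor per dataset), plus an optional
  slowly varying random cubic baseline, disabled by default because the
  study applies no baseline correction.

Axis default: 400–1800 cm⁻¹ in 2 cm⁻¹ steps (701 channels), a typical
portable-Raman fingerprint region. Designs: the 8-level single-analyte
series at 0.3, 0.5, 0.8, 1, 3, 5, 8, 10 mg/L PS, and the 36-composition
full factorial {0, 1, 5, 10, 50, 100}² mg/L PS × SB numbered in blocks of
constant SB with PS ascending. Replicates default to 5. Concentrations are
mg/L everywhere inside the package; μg/L inputs must be converted at the
I/O boundary.

What the generator does **not** emulate: electromagnetic enhancement
physics, adsorption kinetics and analyte competition, instrument response,
wavenumber calibration drift, cosmic-ray spikes, and any non-Gaussian or
spectrally correlated noise. Passing the emulation bounds therefore shows
that the pipeline recovers concentrations under the assumed measurement
model at realistic noise magnitudes — not that it would reach the same
figures on the original instrument's data.

## Window preprocessing

Calibration rows are per-sample averages of the replicate spectra (the
published predicted-vs-actual panels show one marker per sample); a
per-replicate mode exists but is off by default. Windows are built per
band as center ± k·HWHM with k = 3 by default — wide enough to cover the
visually prominent part of a Lorentzian line; the exact coverage fraction
is a convention, not a tuned quantity. Overlapping intervals are merged,
endpoints are inclusive, and channel membership is decided on the printed
wavenumber with no interpolation. Restriction is a projection (idempotent)
and commutes exactly with replicate averaging.

## The reproduction experiments

Three experiments mirror the study: single-analyte PS calibration with an
independently simulated test series of the same 8 levels; a PS model on
the 36-mixture factorial restricted to PS windows (which contain SB
signal); and the matching SB model. Test sets are fresh synthetic draws of
the same design under a disjoint seed — mirroring "another series" of
solutions — not row splits. The reproduction noise configuration is
σ_mult = 0.03, additive fraction 0.005, no baseline, linear response,
5 replicates; with these magnitudes the 5-replicate-averaged pipeline
lands within the published calibration/test bounds, which act as
one-sided acceptance limits. Each metric is reported as the median over
five seed pairs (calibration seeds base+0…4 vs test seeds base+100…104)
to tame Monte-Carlo variation; the three experiments over five seeds run
in a few seconds on one CPU (8 and 36 averaged samples, 99 and 65 window
channels for PS and SB respectively).

The interference analysis groups the 36 mixture predictions by true
target level (six groups of six) and reports each sample's deviation from
its group mean; within-group deviations sum to zero by construction, and
on noise-free data the maximum deviation is below 1e-6 mg/L once A ≥ 2 —
the package's statement of the claim that the co-solute's overlapping
signal does not perturb the target calibration. Blank (0 mg/L) samples
are retained in calibration and evaluation.

## Known limitations

* The synthetic band libraries and noise magnitudes are design choices,
  not measured properties; conclusions transfer to real spectra only to
  the extent the linear-mixture measurement model holds.
* Only univariate-response PLS1 via NIPALS is provided — no PLS2, SIMPLS,
  kernel PLS, orthogonal signal correction, or VIP scores.
* No baseline correction, smoothing or normalization is implemented, since
  the reproduced workflow uses none; spectra needing them must be cleaned
  upstream.
* Prediction uncertainty (e.g. bootstrap intervals) and detection-limit
  estimation are out of scope.
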