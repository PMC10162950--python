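# Methods

This note documents the models, numerical choices and limitations behind
the package, in the order data flows through it.

## The quantification model

A Raman spectrum of a mixture is modeled as a non-negative linear
combination of endmember spectra: for voxel *i*,

    y_i = X β_i + e_i,

where `y_i` is the preprocessed m-channel spectrum, `X` the m × n
calibration matrix whose column k is the spectrum of one concentration
unit of component k, `β_i` the concentration vector and `e_i` unmodeled
residual. The estimator is least squares with β ≥ 0 (Lawson–Hanson active
set, `scipy.optimize.nnls`); an unconstrained OLS solver (QR/SVD via
`numpy.linalg.lstsq`, never the literal normal-equations inverse) is
available for diagnostics. The model assumes the Raman response is linear
in concentration and that mixture spectra add ideally; both assumptions
are exact in the synthetic generator and are the calibration premise for
real data.

Columns of X are internally rescaled to unit ℓ₂ norm and the coefficients
scaled back. This is an exact reparametrization — a test asserts equality
with the raw-unit solve to 1e-8 — but it keeps the solve well conditioned
when the cytochrome c column is present: resonance enhancement at 532 nm
makes that column roughly a thousand-fold stronger per unit mass than the
others, and the column is calibrated in µg/mL for the same reason.

A `bayes_unmix` variant provides uncertainty: independent half-Gaussian
priors (mean 0, SD `prior_sd`, truncated at 0) with a Gaussian noise
model give a conjugate Gaussian posterior that is truncated to the
non-negative orthant by sampling — batched rejection from the untruncated
posterior with a coordinate-wise Gibbs fallback when acceptance is poor.
No specific prior family is canonical for this kind of confidence
assessment; this is the simplest coherent choice, and a calibrated-Bayes
test (truth drawn from the prior) verifies 95% interval coverage.

## Preprocessing (532-nm branch)

Steps run strictly in this order; the stack pipeline is vectorized but is
asserted (by test) to equal the composition of the single-spectrum
operations. Voxels that fail a step are marked invalid and kept as NaN,
never dropped.

1. **Cosmic-ray removal** (filter size 4, dynamic factor 4.1). Channel c
   is a spike iff `x(c) − median_w(c) > 4.1 × 1.4826 × MAD(c)`, with the
   median over ±4 channels and replacement by that median. The MAD is the
   median of deviations about the *center window's* median, taken over a
   wider ±60-channel support: a 9-sample MAD is such a noisy scale
   estimate that ~1% of plain Gaussian-noise channels would be flagged
   (measured); widening the scale support to ±15 × filter_size drops the
   false-flag rate to ~6 × 10⁻⁵ without touching the flag rule or the two
   instrument parameters. Deviations must be taken about the center
   median, not each point's own — the pointwise shortcut underestimates
   the scale near smooth peak tops and mutilates real bands.
2. **Dark-current zeroing**: subtract the minimum over the Rayleigh
   region (−150 to 50 cm⁻¹). Idempotent; refused (with a pointer to the
   785-nm branch) when the axis lacks the region.
3. **Water normalization**: divide by the mean over 3220–3420 cm⁻¹. The
   OH-stretch band of liquid water is assumed constant across the ~5 fL
   sampling volume, so it cancels voxel-specific collection efficiency —
   including depth attenuation, since analyte and water share the optical
   path. This cancellation is exact in the generator and verified to
   1e-8 end to end. Voxels with non-positive water means become invalid.
4. **Matrix-blank subtraction**, channel-wise, after the blank has been
   taken through steps 2–3 itself. Axes must match exactly; an explicit
   linear-interpolation resampler exists, and extrapolation is an error.
   Negative channels are retained — non-negativity belongs to the
   coefficients, not the channels.
5. **Rolling-circle baseline** (shape size 300 channels): morphological
   opening (erosion then dilation with a flat window of radius 300),
   bracketed by Savitzky–Golay order-1 smoothing of width
   ⌈shape_size/10⌉ (odd). Three numerical details matter:
   - the input is smoothed *before* the opening; an erosion of the raw
     noisy signal rides the lower noise envelope and offsets every
     corrected channel upward by a sizeable fraction of the noise SD,
     which translated into tens of percent of concentration bias for
     weak components;
   - the signal is padded by odd reflection before the opening, so the
     disc "rolls off" the spectrum ends instead of plateauing over the
     last shape_size channels (order-1 Savitzky–Golay likewise passes
     linear trends unchanged at the edges);
   - the baseline is re-anchored by the median residual over background
     channels (those where the opening touches the smoothed signal),
     removing the remaining sub-noise-SD offset. The anchor is exactly 0
     for noiseless input and scales linearly, so the exactness and
     unit-scaling guarantees are untouched.
   A flat-window opening on a sloped background inherently leaves a
   residual of order slope × peak width: a FWHM-33 cm⁻¹ unit peak on a
   drift of 1e-4 a.u./cm⁻¹ is recovered to ~1%, but a drift ten times
   steeper degrades recovery to ~10%. Backgrounds curving on scales
   shorter than the 300-channel disc are *removed as if they were peaks*;
   only near-linear backgrounds are corrected to the ≤2% level the tests
   assert.
6. **Crop and mask**: keep the closed interval [400, 3100] cm⁻¹, exclude
   the open silent interval (1800, 2700) — boundary channels survive, so
   channel counts are deterministic.

The **SNR filter** (keep iff CH-stretch max over 2800–3100 ≥ 10 × the SD
over the silent 2200–2600 window; zero-SD voxels pass iff their maximum
is positive) is evaluated on the preprocessed, *uncropped* stack, because
cropping removes the noise window; the mask is attached to the cropped
stack and consumed by `unmix_stack`.

The **785-nm branch** (neratinib-type fluorophores force near-infrared
excitation; the detector range 400–2300 cm⁻¹ excludes the water band)
runs despiking → rolling-circle baseline → standard-normal-variate
scaling → crop. Its coefficients are relative abundances in arbitrary
units; no concentration claim is made, and the qVRI functions report
volumetric class fractions by argmax classification.

## Calibration

`fit_concentration_series` regresses intensity on concentration per
channel (closed-form simple OLS with intercept). The slope spectrum is
the unit-scaled reference; negative slopes are clipped to 0 (library
spectra are physical emission) and counted; a large intercept triggers a
warning because intercepts capture residual blank that preprocessing
should have removed. `r2_summary` is the median per-channel R² over
channels with slope > 10% of the maximum — channels without signal have
undefined R² and would otherwise drown the summary. The linear range is
reported as the supplied min/max concentrations; no breakpoint detection
is attempted.

`depth_snr_profile` averages the per-voxel SNR statistic per z plane and
fits SNR(z) = A·e^(−z/τ) on log-SNR. Because the statistic takes a max
over ~92 signal channels, pure noise alone produces a floor of
E[max of n N(0,1)] ≈ 2.48, which flattens the measured decay at depth and
inflates τ; the fit subtracts this analytic floor (planes below it are
excluded) while the reported profile stays raw. Depth profiling is only
meaningful on spatially homogeneous specimens: on organoid-like random
fields, plane-to-plane composition fluctuations dominate the decay
signal. `synthetic.make_phantom_truth` provides the uniform
single-component phantom this study design calls for; with it, τ = 40 µm
is recovered to ~6% at SNR 30, and the depth at which the fitted curve
crosses the SNR threshold is reported as the maximum reliable
acquisition depth.

## Deposit detection defaults

Augmented mode appends the parent-drug reference as an extra
arbitrary-unit column and thresholds its coefficient. The default
threshold is adaptive: 5 × the 84.13th percentile of the drug
coefficients across voxels. Drug-free voxels carry `max(0, noise)`
coefficients — NNLS zeroes about half of them, so a MAD would collapse to
0 — and for that half-truncated distribution the 84.13th percentile
equals the underlying noise SD. Sparse real deposits barely move the
percentile; on noiseless drug-free stacks the threshold is 0 and the
strict `>` comparison flags nothing.

Residual mode flags voxels whose biomolecule-only residual norm exceeds
5 × the stack median. This is a deep-anomaly detector: the drug signal
must dominate the whole-spectrum noise residual (~σ√m), so a deposit
whose per-channel amplitude is 10 × σ raises the residual norm only
~1.8-fold and stays invisible at the default k = 5. Tests exercise
residual mode at 40 × σ, where it attains full recall at precision 1;
augmented mode is the default whenever a reference spectrum exists and is
exact at 10 × σ.

Particle sizing labels 3-D connected components (26-connectivity by
default, 6 selectable), reports voxel counts, volumes (count × dz·dy·dx)
and centroids, and flags particles below 3,500 µm³ as
intracellular-scale — a size label relative to a typical hepatocyte, not
a biological claim. The kernel-density drug–biomolecule context uses a
Gaussian KDE with Scott's rule and normalizes the gridded density to
integrate to 1.

## Synthetic data: what it does and does not emulate

The generator renders, per voxel,

    raw = dark + a(z) · (Σ_k c_k s_k + blank + water [+ drug]) + noise,

with `a(z) = exp(−z·dz/τ)`, Gaussian peak endmembers (positions follow
canonical band assignments; cytochrome c at 1000 × per-mass intensity),
a single broad water Gaussian at 3400 cm⁻¹ (FWHM 200, constant amplitude
— the internal-standard assumption made literal), a smooth
agarose/PBS-like blank with a gentle linear drift, constant detector dark
current, white Gaussian detector noise, optional logged cosmic-ray
spikes, and optional drug signal at deposit voxels. Concentration fields
are smoothed Gaussian random fields with means and SDs inside the phantom
calibration ranges (protein 100 ± 30 mg/mL, etc.); the default full-stack
scene is 5 × 20 × 20 voxels at (10, 2, 2) µm pitch on a 1100-channel
0–3600 cm⁻¹ axis, sized so the complete pipeline runs in seconds. The
two-condition generator constructs the lipid field from the standardized
protein field plus an orthogonalized noise field, so the sample
correlation equals the requested value (0.1 control, 0.7 treated)
exactly up to rare clipping at 0.

"SNR n" means the raw noise SD is set to (mean voxel CH-window signal
height)/n on the noiseless render. All generators are pure functions of
their parameters and a seed.

Deliberately not modeled: wavelength-dependent optics (point-spread
function, NA), shot noise (noise is additive, not signal-scaled),
spectrometer wavenumber error, fluorescence backgrounds beyond smooth
drifts, water-content variation between voxels, and nonlinear
concentration response. Passing tests therefore demonstrate the
*pipeline's* correctness under the stated physics — linearity, shared
attenuation of analyte and water, additive noise — not robustness to
every instrument artifact of real acquisitions.

## Problem sizes used in tests and the acceptance script

Solver oracles use 50 random 2-component systems against a step-0.01
non-negative grid search and 50 systems against the explicit
normal-equations solve. Recovery studies use a 5 × 20 × 20 stack at
SNR 20 (six components); false-signal studies a 3 × 10 × 10 stack with
two components held at zero; attenuation studies 3–6 plane stacks at
τ = 40 µm; despiking 10 seeds × 50 logged spikes on 2 × 4 × 4 stacks at
SNR 50; deposits 12 voxels in a 4 × 10 × 10 stack; co-localization 10
seeds × two conditions of 3 × 16 × 16 stacks at SNR 30. These sizes give
stable statistics (thousands of voxels per condition) while keeping the
full suite and the acceptance script each around a minute or two of
single-CPU time.

## Known limitations

- The rolling-circle step corrects only backgrounds flatter than the
  300-channel disc; steep or strongly curved fluorescence is partially
  absorbed into analyte channels (quantified above).
- Concentrations above the calibrated phantom range are extrapolations
  of the linear model; the package reports them without flagging.
- `bayes_unmix` quantifies coefficient uncertainty given the linear
  model and known noise SD; it does not propagate calibration-slope
  uncertainty.
- The 785-nm branch yields arbitrary units only; cross-specimen
  comparability relies on SNV scaling holding across specimens.
- Stage tracking (`raw → preprocessed → cropped`) guards against
  double-processing, but the package cannot detect a stack preprocessed
  by other software with different windows.
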