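"""Per-voxel spectral preprocessing.

The 532-nm pipeline applies, in order: cosmic-ray removal, Rayleigh-region
dark-current zeroing, normalization of the water OH-stretch band mean to 1
(the internal standard that turns arbitrary counts into water-relative
units), matrix-blank subtraction, rolling-circle baseline correction, and
cropping with exclusion of the biologically silent region. The 785-nm
branch, whose detector range (400-2300 cm^-1) excludes the water band,
substitutes standard-normal-variate scaling after baseline correction.

All single-spectrum operations are pure functions on :class:`Spectrum`;
the stack pipeline applies the identical arithmetic vectorized over voxels,
so ``preprocess_stack`` equals the composition of the single-spectrum steps.
Voxels that fail a step (e.g. non-positive water-band mean) are marked in
the stack's ``invalid_mask``, never dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .datatypes import (
    AxisMismatchError,
    HyperspectralStack,
    NormalizationError,
    RamanValidationError,
    Spectrum,
    WavenumberAxis,
)

__all__ = [
    "PreprocessConfig",
    "remove_cosmic_rays",
    "zero_dark_current",
    "normalize_to_water",
    "subtract_blank",
    "rolling_circle_baseline",
    "crop_and_mask",
    "snv_scale",
    "resample_spectrum",
    "preprocess_blank",
    "preprocess_stack",
    "snr_filter",
]

#: MAD -> sigma equivalence factor for Gaussian noise.
MAD_TO_SIGMA = 1.4826


@dataclass
class PreprocessConfig:
    """Numeric defaults of the preprocessing pipeline.

    Windows are wavenumber intervals in cm^-1, treated as closed ``[lo,
    hi]`` except the silent region, which is excluded as the open interval
    so its boundary channels survive cropping.
    """

    cosmic_filter_size: int = 4
    cosmic_dynamic_factor: float = 4.1
    rayleigh_window: tuple[float, float] = (-150.0, 50.0)
    water_window: tuple[float, float] = (3220.0, 3420.0)
    baseline_shape_size: int = 300
    crop_window: tuple[float, float] = (400.0, 3100.0)
    silent_mask: tuple[float, float] = (1800.0, 2700.0)
    snr_signal_window: tuple[float, float] = (2800.0, 3100.0)
    snr_noise_window: tuple[float, float] = (2200.0, 2600.0)
    snr_factor: float = 10.0
    #: 785-nm near-infrared detector range, cm^-1.
    range_785: tuple[float, float] = (400.0, 2300.0)

    def __post_init__(self) -> None:
        if self.cosmic_filter_size < 1:
            raise RamanValidationError("cosmic_filter_size must be >= 1")
        if self.cosmic_dynamic_factor <= 0:
            raise RamanValidationError("cosmic_dynamic_factor must be > 0")
        if self.baseline_shape_size < 1:
            raise RamanValidationError("baseline_shape_size must be >= 1")
        if self.snr_factor <= 0:
            raise RamanValidationError("snr_factor must be > 0")
        for name in ("rayleigh_window", "water_window", "crop_window", "silent_mask",
                     "snr_signal_window", "snr_noise_window", "range_785"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise RamanValidationError(f"{name} must satisfy lo < hi, got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))

    @classmethod
    def from_json(cls, path) -> "PreprocessConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# array-level kernels (trailing axis = spectral channel) shared by the
# single-spectrum operations and the vectorized stack pipeline


#: Half-width of the robust-scale (MAD) support, in multiples of the
#: despiking median half-width. A MAD estimated from only 2*filter_size+1
#: samples is so noisy that ~1% of ordinary noise channels would be flagged;
#: widening the scale window (median window unchanged) removes that
#: estimator-noise tail while leaving genuine single-channel spikes intact.
MAD_SUPPORT_FACTOR = 15


def _despike(values: np.ndarray, filter_size: int, dynamic_factor: float
             ) -> tuple[np.ndarray, np.ndarray]:
    """Median/MAD spike replacement along the trailing axis.

    A channel is a spike iff its excess over the local +-filter_size median
    exceeds ``dynamic_factor`` robust standard deviations, estimated as
    ``MAD_TO_SIGMA x MAD`` of the deviations about that median over a wider
    (+-MAD_SUPPORT_FACTOR x filter_size) support. Flagged channels are
    replaced by the window median; nothing else is touched.
    """
    if filter_size < 1:
        raise RamanValidationError("filter_size must be >= 1")
    window = 2 * filter_size + 1
    m = values.shape[-1]
    if m < window:
        raise RamanValidationError(
            f"spectrum of {m} channels is shorter than the "
            f"{window}-channel despiking window"
        )
    flat = values.reshape(-1, m)
    mad_half = min(MAD_SUPPORT_FACTOR * filter_size, m - 1)
    out = np.empty_like(flat)
    spikes = np.empty(flat.shape, dtype=bool)
    chunk = max(1, int(2**26 // (m * (2 * mad_half + 1))))  # ~256 MB working set
    for start in range(0, flat.shape[0], chunk):
        block = flat[start:start + chunk]
        padded = np.pad(block, [(0, 0), (filter_size, filter_size)], mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(padded, window, axis=-1)
        med = np.median(win, axis=-1)
        # scale estimation runs in float32: spikes are orders of magnitude
        # above threshold, so rounding in the MAD cannot change a decision
        b32 = block.astype(np.float32)
        padded = np.pad(b32, [(0, 0), (mad_half, mad_half)], mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(padded, 2 * mad_half + 1, axis=-1)
        # deviations about the center's median, over the wide support
        mad = np.median(np.abs(win - med[..., None].astype(np.float32)), axis=-1)
        hit = (block - med) > dynamic_factor * MAD_TO_SIGMA * mad
        out[start:start + chunk] = np.where(hit, med, block)
        spikes[start:start + chunk] = hit
    return out.reshape(values.shape), spikes.reshape(values.shape)


def _window_idx(axis: WavenumberAxis, window: tuple[float, float], what: str) -> np.ndarray:
    return axis.window_indices(window[0], window[1], what)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Moving average with trend-preserving edges (local linear fit there)."""
    if window < 3:
        return values
    from scipy.signal import savgol_filter

    # polyorder-1 Savitzky-Golay equals the moving average on symmetric
    # interior windows and fits a line at the edges, so ramps pass unchanged
    return savgol_filter(values, window, 1, axis=-1, mode="interp")


def _opening_baseline(values: np.ndarray, shape_size: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rolling-circle background: smoothed morphological opening.

    Returns ``(presmoothed, opened, baseline)``. Opening with a flat disc
    of radius ``shape_size`` channels (erosion then dilation) tracks
    backgrounds varying slower than the disc while passing under peaks
    narrower than it. The input is smoothed first (width
    ``ceil(shape_size/10)``, odd) so the erosion follows the background
    rather than the lower noise envelope — an unsmoothed opening of a noisy
    spectrum would bias the whole corrected spectrum upward by the noise
    amplitude. The same pass then removes the opening's staircase steps.
    ``opened <= presmoothed`` channel-wise by construction.
    """
    if shape_size < 1:
        raise RamanValidationError("shape_size must be >= 1")
    m = values.shape[-1]
    if shape_size >= m:
        raise RamanValidationError(
            f"shape_size {shape_size} must be smaller than the {m}-channel spectrum"
        )
    window = 2 * shape_size + 1
    size = (1,) * (values.ndim - 1) + (window,)
    smooth_w = math.ceil(shape_size / 10)
    smooth_w += 1 - smooth_w % 2  # odd
    pre = _smooth(values, smooth_w)
    # odd reflection continues the boundary trend, so the disc can "roll
    # off" the ends instead of plateauing over the last shape_size channels
    pad = [(0, 0)] * (values.ndim - 1) + [(shape_size, shape_size)]
    padded = np.pad(pre, pad, mode="reflect", reflect_type="odd")
    opened = ndimage.grey_opening(padded, size=size, mode="nearest")
    opened = opened[..., shape_size:-shape_size]
    baseline = _smooth(opened, smooth_w)
    # Re-anchor: even after smoothing, the erosion tracks the lower noise
    # envelope, leaving the whole corrected spectrum offset upward by a
    # fraction of the noise SD. The median residual over background
    # channels (where the opening touches the smoothed signal) estimates
    # that offset; it is exactly 0 for noiseless input, so exactness and
    # homogeneity in overall scale are preserved.
    lift = pre - opened
    bg = lift <= np.median(lift, axis=-1, keepdims=True)
    resid = np.where(bg, values - baseline, np.nan)
    offset = np.nanmedian(resid, axis=-1)[..., None]
    baseline = baseline + offset
    return pre, opened, baseline


# ---------------------------------------------------------------------------
# single-spectrum operations


def remove_cosmic_rays(s: Spectrum, filter_size: int = 4, dynamic_factor: float = 4.1
                       ) -> Spectrum:
    """Replace cosmic-ray spike channels by the local median."""
    cleaned, spikes = _despike(s.intensity, filter_size, dynamic_factor)
    return s.replace(intensity=cleaned, despiked_channels=int(spikes.sum()))


def zero_dark_current(s: Spectrum, rayleigh_window: tuple[float, float] = (-150.0, 50.0)
                      ) -> Spectrum:
    """Subtract the minimum over the Rayleigh region (detector dark current).

    Raises when the window misses the axis — the 785-nm branch, whose range
    starts at 400 cm^-1, skips this step.
    """
    try:
        idx = _window_idx(s.axis, rayleigh_window, "Rayleigh window")
    except RamanValidationError as exc:
        raise RamanValidationError(
            f"{exc}; a spectrum without the Rayleigh region belongs to the 785-nm branch"
        ) from exc
    return s.replace(intensity=s.intensity - s.intensity[idx].min())


def normalize_to_water(s: Spectrum, water_window: tuple[float, float] = (3220.0, 3420.0)
                       ) -> Spectrum:
    """Divide by the mean intensity over the water OH-stretch band.

    After this step the water-window mean is exactly 1, making the liquid
    water in the confocal voxel the internal intensity standard.
    """
    idx = _window_idx(s.axis, water_window, "water window")
    mean = float(s.intensity[idx].mean())
    if not np.isfinite(mean) or mean <= 0:
        raise NormalizationError(
            f"water-window mean {mean!r} is not positive; cannot normalize"
        )
    return s.replace(intensity=s.intensity / mean, water_normalized=True)


def subtract_blank(s: Spectrum, blank: Spectrum) -> Spectrum:
    """Channel-wise matrix-blank subtraction (blank must share the axis).

    Negative values are retained, not clipped; non-negativity is enforced
    later on the unmixing coefficients rather than on channels.
    """
    s.axis.require_match(blank.axis, "blank subtraction")
    return s.replace(intensity=s.intensity - blank.intensity, blank_subtracted=True)


def rolling_circle_baseline(s: Spectrum, shape_size: int = 300
                            ) -> tuple[Spectrum, Spectrum]:
    """Rolling-circle background removal; returns (corrected, baseline)."""
    _, _, baseline = _opening_baseline(s.intensity, shape_size)
    corrected = s.replace(intensity=s.intensity - baseline, baseline_corrected=True)
    return corrected, Spectrum(s.axis, baseline, meta={"kind": "baseline"})


def crop_and_mask(s: Spectrum,
                  crop_window: tuple[float, float] = (400.0, 3100.0),
                  silent_mask: tuple[float, float] = (1800.0, 2700.0)) -> Spectrum:
    """Restrict to the cropped fingerprint + CH-stretch grid.

    Keeps channels inside the closed crop window and outside the open
    silent interval (so channels exactly at 1800 or 2700 cm^-1 survive).
    """
    keep = crop_keep_mask(s.axis, crop_window, silent_mask)
    return s.replace(intensity=s.intensity[keep],
                     axis=WavenumberAxis(s.axis.values[keep]), cropped=True)


def crop_keep_mask(axis: WavenumberAxis,
                   crop_window: tuple[float, float] = (400.0, 3100.0),
                   silent_mask: tuple[float, float] | None = (1800.0, 2700.0)) -> np.ndarray:
    """Boolean channel-survival mask of the crop/silent-region rule."""
    w = axis.values
    keep = (w >= crop_window[0]) & (w <= crop_window[1])
    if silent_mask is not None:
        keep &= ~((w > silent_mask[0]) & (w < silent_mask[1]))
    if not keep.any():
        raise RamanValidationError(
            f"cropping to {crop_window} with silent mask {silent_mask} leaves no channel"
        )
    return keep


def snv_scale(s: Spectrum) -> Spectrum:
    """Standard-normal-variate scaling: mean 0, population SD 1."""
    sd = float(s.intensity.std())
    if sd <= 0 or not np.isfinite(sd):
        raise NormalizationError("constant spectrum cannot be SNV scaled (zero variance)")
    return s.replace(intensity=(s.intensity - s.intensity.mean()) / sd, snv_scaled=True)


def resample_spectrum(s: Spectrum, axis: WavenumberAxis) -> Spectrum:
    """Linear interpolation onto a new grid; extrapolation is refused."""
    lo, hi = s.axis.values[0], s.axis.values[-1]
    if axis.values[0] < lo or axis.values[-1] > hi:
        raise RamanValidationError(
            f"target axis [{axis.values[0]}, {axis.values[-1]}] extends beyond the "
            f"measured range [{lo}, {hi}]; refusing to extrapolate"
        )
    return Spectrum(axis, np.interp(axis.values, s.axis.values, s.intensity),
                    meta={**s.meta, "resampled": True})


def preprocess_blank(blank: Spectrum, config: PreprocessConfig,
                     target_axis: WavenumberAxis | None = None) -> Spectrum:
    """Take the matrix blank through dark-current zeroing + water normalization.

    The blank must be processed by the same prior steps as the specimen
    before channel-wise subtraction. If its grid differs from
    ``target_axis`` it is linearly resampled first (explicitly; never
    silently inside an arithmetic step).
    """
    if target_axis is not None and not blank.axis.matches(target_axis):
        blank = resample_spectrum(blank, target_axis)
    blank = zero_dark_current(blank, config.rayleigh_window)
    return normalize_to_water(blank, config.water_window)


# ---------------------------------------------------------------------------
# stack pipeline


def _baseline_correct_valid(data: np.ndarray, invalid: np.ndarray,
                            shape_size: int) -> np.ndarray:
    """Rolling-circle correction that tolerates NaN (invalid) voxels."""
    finite = np.where(invalid[..., None], 0.0, data)
    _, _, baseline = _opening_baseline(finite, shape_size)
    out = finite - baseline
    out[invalid] = np.nan
    return out


def _stack_window_idx(stack: HyperspectralStack, window, what: str) -> np.ndarray:
    return stack.axis.window_indices(window[0], window[1], what)


def snr_filter(stack: HyperspectralStack, config: PreprocessConfig | None = None
               ) -> np.ndarray:
    """Voxel SNR mask: signal-window max >= snr_factor x silent-region SD.

    Evaluated on the preprocessed, uncropped spectrum (the noise window
    lies inside the region removed by cropping); the resulting mask is then
    carried onto the cropped stack. Zero-SD voxels pass iff their signal
    maximum is positive; voxels already invalid are excluded.
    """
    config = config or PreprocessConfig()
    sig_idx = _stack_window_idx(stack, config.snr_signal_window, "SNR signal window")
    noise_idx = _stack_window_idx(stack, config.snr_noise_window, "SNR noise window")
    data = stack.intensities
    sig_max = data[..., sig_idx].max(axis=-1)
    noise_sd = data[..., noise_idx].std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore"):
        mask = np.where(noise_sd > 0,
                        sig_max >= config.snr_factor * noise_sd,
                        sig_max > 0)
    mask &= np.isfinite(sig_max) & np.isfinite(noise_sd)
    if stack.invalid_mask is not None:
        mask &= ~stack.invalid_mask
    return mask


def preprocess_stack(stack: HyperspectralStack, blank: Spectrum | None,
                     config: PreprocessConfig | None = None, branch: int = 532,
                     crop: bool = True) -> HyperspectralStack:
    """Run the full per-voxel pipeline on a raw stack.

    532 branch: despike -> dark-current zero -> water normalization ->
    blank subtraction -> rolling-circle baseline -> crop/silent-mask.
    785 branch: despike -> rolling-circle baseline -> SNV -> crop to the
    near-infrared detector range (no water band, no blank step).

    The SNR mask is evaluated just before cropping (while the silent and
    CH-stretch windows still exist) and stored in ``meta["snr_mask"]``.
    Voxels failing a step are marked in ``invalid_mask`` and set to NaN.
    """
    config = config or PreprocessConfig()
    stack.require_stage("raw", "preprocess_stack")
    if branch not in (532, 785):
        raise RamanValidationError(f"branch must be 532 or 785, got {branch}")

    data = np.asarray(stack.intensities, dtype=np.float64)
    invalid = np.zeros(stack.spatial_shape, dtype=bool)
    if stack.invalid_mask is not None:
        invalid |= stack.invalid_mask

    data, _ = _despike(data, config.cosmic_filter_size, config.cosmic_dynamic_factor)

    if branch == 532:
        ray_idx = _stack_window_idx(stack, config.rayleigh_window, "Rayleigh window")
        data = data - data[..., ray_idx].min(axis=-1, keepdims=True)

        water_idx = _stack_window_idx(stack, config.water_window, "water window")
        water_mean = data[..., water_idx].mean(axis=-1, keepdims=True)
        bad = ~np.isfinite(water_mean[..., 0]) | (water_mean[..., 0] <= 0)
        invalid |= bad
        with np.errstate(divide="ignore", invalid="ignore"):
            data = np.where(bad[..., None], np.nan, data / water_mean)
        # internal-standard invariant: every valid voxel now has water-window
        # mean exactly 1 (up to float rounding)
        valid = ~invalid
        if valid.any():
            means = data[valid][:, water_idx].mean(axis=-1)
            assert np.allclose(means, 1.0, atol=1e-9), "water normalization failed"

        if blank is None:
            raise RamanValidationError("the 532-nm branch requires a matrix blank spectrum")
        blank_pre = preprocess_blank(blank, config, target_axis=stack.axis)
        data = data - blank_pre.intensity

        data = _baseline_correct_valid(data, invalid, config.baseline_shape_size)
    else:
        data = _baseline_correct_valid(data, invalid, config.baseline_shape_size)
        sd = data.std(axis=-1, keepdims=True)
        bad = ~np.isfinite(sd[..., 0]) | (sd[..., 0] <= 0)
        invalid |= bad
        with np.errstate(divide="ignore", invalid="ignore"):
            data = np.where(bad[..., None], np.nan,
                            (data - data.mean(axis=-1, keepdims=True)) / sd)

    meta = dict(stack.meta)
    meta["branch"] = branch
    out = HyperspectralStack(axis=stack.axis, intensities=data,
                             voxel_pitch=stack.voxel_pitch, stage="preprocessed",
                             meta=meta, invalid_mask=invalid)
    if branch == 532:
        try:
            meta["snr_mask"] = snr_filter(out, config)
        except RamanValidationError:
            pass  # axis lacks the SNR windows; caller may filter differently
    if not crop:
        return out

    if branch == 532:
        keep = crop_keep_mask(stack.axis, config.crop_window, config.silent_mask)
    else:
        keep = crop_keep_mask(stack.axis, config.range_785, None)
    out = HyperspectralStack(axis=WavenumberAxis(stack.axis.values[keep]),
                             intensities=data[..., keep],
                             voxel_pitch=stack.voxel_pitch, stage="cropped",
                             meta=meta, invalid_mask=invalid)
    return out
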