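"""Tissue-phantom calibration: concentration-response fits and SNR-vs-depth.

Each endmember's unit-scaled reference spectrum is the per-channel slope of
intensity against phantom concentration, so that a later unmixing
coefficient of value ``c`` reads directly in the component's concentration
unit (a.u. per 1 mg/mL or per 1 ug/mL). Fits include an intercept, but only
slopes enter the library: the intercept captures residual blank signal that
preprocessing should already have removed, and a large one is a QC warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    HyperspectralStack,
    RamanValidationError,
    ReferenceLibrary,
    Spectrum,
    WavenumberAxis,
)
from .preprocess import (
    PreprocessConfig,
    crop_and_mask,
    preprocess_blank,
    remove_cosmic_rays,
    rolling_circle_baseline,
    subtract_blank,
    normalize_to_water,
    zero_dark_current,
)

__all__ = [
    "CalibrationSeries",
    "CalibrationFit",
    "DepthProfile",
    "preprocess_series",
    "fit_concentration_series",
    "build_reference_library",
    "depth_snr_profile",
]


@dataclass
class CalibrationSeries:
    """Phantom spectra at known concentrations for one component."""

    component_name: str
    concentration_unit: str
    points: list[tuple[float, Spectrum]]

    def __post_init__(self) -> None:
        if len({round(c, 12) for c, _ in self.points}) < 3:
            raise RamanValidationError(
                f"series {self.component_name!r} needs >= 3 distinct concentrations"
            )
        if any(c < 0 for c, _ in self.points):
            raise RamanValidationError("concentrations must be non-negative")
        axis = self.points[0][1].axis
        for _, s in self.points[1:]:
            axis.require_match(s.axis, f"calibration series {self.component_name!r}")

    @property
    def axis(self) -> WavenumberAxis:
        return self.points[0][1].axis

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=np.float64)

    @property
    def intensity_matrix(self) -> np.ndarray:
        """(n_points, m) matrix of intensities."""
        return np.vstack([s.intensity for _, s in self.points])


@dataclass
class CalibrationFit:
    """Per-channel linear concentration response of one component."""

    component_name: str
    concentration_unit: str
    axis: WavenumberAxis
    slope_spectrum: np.ndarray      # the unit-scaled reference (clipped >= 0)
    intercept_spectrum: np.ndarray
    r2_per_channel: np.ndarray
    r2_summary: float
    linear_range: tuple[float, float]
    n_clipped_channels: int = 0


@dataclass
class DepthProfile:
    """Mean voxel SNR per z plane, with an optional exponential decay fit."""

    depths_um: np.ndarray
    snr: np.ndarray
    attenuation_fit: tuple[float, float] | None = None  # (amplitude, tau um)
    max_reliable_depth_um: float | None = None


def preprocess_series(series: CalibrationSeries, blank: Spectrum,
                      config: PreprocessConfig | None = None) -> CalibrationSeries:
    """Push raw phantom spectra through the 532-nm pipeline (incl. crop)."""
    config = config or PreprocessConfig()
    blank_pre = preprocess_blank(blank, config, target_axis=series.axis)
    out = []
    for c, s in series.points:
        s = remove_cosmic_rays(s, config.cosmic_filter_size, config.cosmic_dynamic_factor)
        s = zero_dark_current(s, config.rayleigh_window)
        s = normalize_to_water(s, config.water_window)
        s = subtract_blank(s, blank_pre)
        s, _ = rolling_circle_baseline(s, config.baseline_shape_size)
        s = crop_and_mask(s, config.crop_window, config.silent_mask)
        out.append((c, s))
    return CalibrationSeries(series.component_name, series.concentration_unit, out)


def fit_concentration_series(series: CalibrationSeries) -> CalibrationFit:
    """Per-channel OLS of intensity on concentration.

    Negative-slope channels are clipped to 0 (library spectra are physical,
    non-negative emission) and counted. ``r2_summary`` is the median
    per-channel R^2 over informative channels (slope > 10% of max slope).
    """
    c = series.concentrations
    y = series.intensity_matrix
    if not np.any(np.abs(y) > 0):
        raise RamanValidationError("all-zero series cannot be calibrated")
    c_centered = c - c.mean()
    denom = float(c_centered @ c_centered)
    slope = (c_centered @ (y - y.mean(axis=0))) / denom
    intercept = y.mean(axis=0) - slope * c.mean()

    fitted = np.outer(c, slope) + intercept
    ss_res = ((y - fitted) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)

    n_clipped = int((slope < 0).sum())
    slope_clipped = np.clip(slope, 0.0, None)
    if n_clipped:
        warnings.warn(
            f"{series.component_name}: clipped {n_clipped} negative-slope channels to 0",
            stacklevel=2,
        )
    peak = slope_clipped.max()
    informative = slope_clipped > 0.1 * peak if peak > 0 else np.zeros_like(slope, bool)
    r2_summary = float(np.nanmedian(r2[informative])) if informative.any() else float("nan")

    scale = np.abs(slope_clipped).max()
    if scale > 0 and np.abs(intercept).max() > 0.5 * scale * max(series.concentrations.max(), 1.0):
        warnings.warn(
            f"{series.component_name}: large calibration intercept suggests residual "
            "blank signal; check preprocessing", stacklevel=2,
        )
    return CalibrationFit(
        component_name=series.component_name,
        concentration_unit=series.concentration_unit,
        axis=series.axis,
        slope_spectrum=slope_clipped,
        intercept_spectrum=intercept,
        r2_per_channel=r2,
        r2_summary=r2_summary,
        linear_range=(float(c.min()), float(c.max())),
        n_clipped_channels=n_clipped,
    )


def build_reference_library(fits: list[CalibrationFit],
                            axis: WavenumberAxis | None = None) -> ReferenceLibrary:
    """Assemble the calibration matrix X column-wise from unit-scaled fits."""
    if not fits:
        raise RamanValidationError("need at least one calibration fit")
    axis = axis or fits[0].axis
    for f in fits:
        axis.require_match(f.axis, f"library assembly ({f.component_name})")
    names = [f.component_name for f in fits]
    if len(set(names)) != len(names):
        raise RamanValidationError(f"duplicate component names {names}")
    return ReferenceLibrary(
        axis=axis,
        names=names,
        spectra=np.column_stack([f.slope_spectrum for f in fits]),
        units=[f.concentration_unit for f in fits],
    )


def _noise_max_floor(n_channels: int) -> float:
    """E[max of n iid standard normals]: the SNR floor of a pure-noise voxel."""
    from scipy import integrate, stats

    val, _ = integrate.quad(
        lambda x: x * stats.norm.pdf(x) * stats.norm.cdf(x) ** (n_channels - 1),
        -8, 8)
    return float(n_channels * val)


def depth_snr_profile(stack: HyperspectralStack, config: PreprocessConfig | None = None,
                      fit_attenuation: bool = True) -> DepthProfile:
    """Mean voxel SNR per z plane of a preprocessed phantom stack.

    SNR per voxel = (signal-window max) / (silent-window SD), averaged over
    the plane. When >= 3 planes have positive SNR, an exponential decay
    ``SNR(z) = A exp(-z/tau)`` is fitted by least squares on log SNR, and
    the depth at which the fit crosses ``snr_factor`` is reported as the
    maximum reliable acquisition depth.

    Because the statistic takes a max over the signal window, pure noise
    alone produces a floor of E[max of n N(0,1)] (~2.5 for ~90 channels),
    which flattens the measured decay at depth and inflates tau. The fit
    therefore runs on the floor-subtracted profile (planes that fall below
    the floor are excluded); ``snr`` itself is reported uncorrected.
    Meaningful profiles require spatial homogeneity — use phantom stacks,
    where plane-to-plane SNR change is attenuation, not composition.
    """
    config = config or PreprocessConfig()
    sig_idx = stack.axis.window_indices(*config.snr_signal_window, "SNR signal window")
    noise_idx = stack.axis.window_indices(*config.snr_noise_window, "SNR noise window")
    nz = stack.spatial_shape[0]
    dz = stack.voxel_pitch[0]
    depths = np.arange(nz, dtype=np.float64) * dz

    data = stack.intensities
    sig = data[..., sig_idx].max(axis=-1)
    sd = data[..., noise_idx].std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        voxel_snr = np.where(sd > 0, sig / sd, np.inf)
    if stack.invalid_mask is not None:
        voxel_snr = np.where(stack.invalid_mask, np.nan, voxel_snr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        snr = np.nanmean(np.where(np.isfinite(voxel_snr), voxel_snr, np.nan), axis=(1, 2))

    fit = None
    max_depth = None
    floor = _noise_max_floor(len(sig_idx))
    corrected = snr - floor
    positive = np.isfinite(corrected) & (corrected > 0)
    if fit_attenuation and nz >= 3 and positive.sum() >= 3:
        coef = np.polyfit(depths[positive], np.log(corrected[positive]), 1)
        slope, log_a = coef
        if slope < 0:
            tau = -1.0 / slope
            amplitude = float(np.exp(log_a))
            fit = (amplitude, float(tau))
            if amplitude > config.snr_factor:
                max_depth = float(tau * np.log(amplitude / config.snr_factor))
    return DepthProfile(depths_um=depths, snr=snr, attenuation_fit=fit,
                        max_reliable_depth_um=max_depth)
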