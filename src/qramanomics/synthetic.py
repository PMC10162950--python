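"""Synthetic Raman fixtures with full ground truth.

Everything the pipeline consumes can be generated here, seeded and
deterministic: component peak spectra (stand-ins for measured endmember
references), the broad water OH-stretch band used as internal standard,
matrix-blank backgrounds, phantom calibration series over the
bio-relevant concentration ranges (protein 10-300 mg/mL, saturated lipid
5-80, monounsaturated lipid 5-50, nucleic acids 10-60, glycogen 10-100
mg/mL, cytochrome c in ug/mL with its ~1000-fold resonance-enhanced
intensity), depth-attenuated organoid-like stacks with spatially smooth
concentration fields, xenobiotic deposit inclusions, and cosmic-ray
spikes with an exact injection log.

The water band is modeled as a single broad Gaussian at 3400 cm^-1 (FWHM
200) of constant amplitude across voxels — the assumption that water
content is constant within the ~5 fL confocal sampling volume is what
makes water a usable internal standard. Depth attenuation multiplies
analyte, blank and water signal alike (they share the optical path), which
is exactly why water normalization cancels it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationSeries
from .datatypes import (
    HyperspectralStack,
    RamanValidationError,
    ReferenceLibrary,
    Spectrum,
    WavenumberAxis,
)
from .preprocess import PreprocessConfig

__all__ = [
    "PeakModel",
    "GroundTruth",
    "make_axis",
    "make_component_spectrum",
    "default_peak_models",
    "drug_peak_model",
    "metabolite_peak_model",
    "water_band",
    "blank_spectrum",
    "simulate_blank",
    "simulate_phantom_series",
    "default_concentration_grid",
    "make_organoid_truth",
    "make_two_condition_truths",
    "simulate_organoid_stack",
    "noise_sd_for_snr",
    "simulate_snr_labeled_stack",
    "inject_cosmic_rays",
    "reference_library_from_models",
]

DEFAULT_VOXEL_PITCH = (10.0, 2.0, 2.0)  # (dz, dy, dx) um
DEFAULT_WATER_AMPLITUDE = 10.0          # raw a.u. of the OH-stretch band peak
DEFAULT_DARK_OFFSET = 2.0               # constant detector dark current, a.u.

#: Phantom concentration grids per component (unit in the model).
DEFAULT_CONCENTRATIONS = {
    "protein": (10.0, 300.0),
    "DPPC": (5.0, 80.0),
    "POPC": (5.0, 50.0),
    "nucleic acids": (10.0, 60.0),
    "glycogen": (10.0, 100.0),
    "cytochrome c": (10.0, 100.0),
}


@dataclass(frozen=True)
class PeakModel:
    """A component's spectrum as a sum of line shapes.

    ``unit_scale`` is the peak-height multiplier per 1 concentration unit,
    so ``c * spectrum`` is the raw signal of concentration c.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]  # (center cm^-1, FWHM cm^-1, rel height)
    unit_scale: float
    concentration_unit: str = "mg/mL"
    lineshape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise RamanValidationError(f"unknown lineshape {self.lineshape!r}")
        for center, fwhm, height in self.peaks:
            if fwhm <= 0 or height <= 0:
                raise RamanValidationError(
                    f"{self.name}: peak FWHM and height must be positive"
                )


@dataclass
class GroundTruth:
    """The latent state a simulated stack is rendered from."""

    fields: dict[str, np.ndarray]          # component -> (nz, ny, nx) concentrations
    deposit_mask: np.ndarray | None = None
    tau_um: float | None = None            # attenuation length; None = no attenuation
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.fields.values()}
        if len(shapes) != 1:
            raise RamanValidationError("all concentration fields must share one shape")
        for name, f in self.fields.items():
            if np.any(f < 0):
                raise RamanValidationError(f"field {name!r} has negative concentrations")
        if self.deposit_mask is not None:
            self.deposit_mask = np.asarray(self.deposit_mask, dtype=bool)
            if self.deposit_mask.shape != next(iter(shapes)):
                raise RamanValidationError("deposit mask shape must match fields")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.fields.values())).shape


def make_axis(start: float = 0.0, stop: float = 3600.0, n_channels: int = 1100
              ) -> WavenumberAxis:
    """The default instrument grid: 0-3600 cm^-1, ~3.3 cm^-1 per channel."""
    return WavenumberAxis(np.linspace(start, stop, n_channels))


def _lineshape(axis_values: np.ndarray, center: float, fwhm: float, height: float,
               kind: str) -> np.ndarray:
    if kind == "gaussian":
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return height * np.exp(-0.5 * ((axis_values - center) / sigma) ** 2)
    half = fwhm / 2.0
    return height * half**2 / ((axis_values - center) ** 2 + half**2)


def make_component_spectrum(model: PeakModel, axis: WavenumberAxis) -> Spectrum:
    """Render a peak model on the grid; 1 unit of concentration worth."""
    lo, hi = axis.values[0], axis.values[-1]
    intensity = np.zeros(len(axis))
    for center, fwhm, height in model.peaks:
        if not lo <= center <= hi:
            raise RamanValidationError(
                f"{model.name}: peak at {center} cm^-1 outside axis [{lo}, {hi}]"
            )
        intensity += _lineshape(axis.values, center, fwhm, height, model.lineshape)
    return Spectrum(axis, intensity * model.unit_scale,
                    meta={"name": model.name, "unit": model.concentration_unit})


def default_peak_models() -> list[PeakModel]:
    """The six-component endmember set used throughout the synthetic studies.

    Peak positions follow the canonical band assignments (phenylalanine
    ring breathing at 1003, CH2 twist ~1300, amide I ~1660, CH stretch
    2850-3010, glycogen skeletal modes 480-940, nucleic-acid backbone
    785/1095, cytochrome c resonance bands 750/1314/1585). Primary peaks
    are distinct enough that the column-normalized calibration matrix is
    well conditioned. Cytochrome c is scaled per ug/mL at ~1000x the per-
    mass intensity of the others, emulating its resonance enhancement at
    532 nm.
    """
    s = 0.003  # baseline peak-height scale, a.u. per (mg/mL)
    return [
        PeakModel("protein", (
            (1003, 16, 0.50), (1250, 60, 0.35), (1450, 40, 0.45),
            (1660, 45, 0.60), (2930, 80, 1.00),
        ), unit_scale=s),
        PeakModel("DPPC", (
            (1064, 20, 0.50), (1130, 20, 0.45), (1296, 24, 0.60),
            (1440, 35, 0.70), (2850, 45, 1.00), (2885, 40, 0.90),
        ), unit_scale=1.3 * s),
        PeakModel("POPC", (
            (1080, 30, 0.40), (1265, 28, 0.50), (1440, 40, 0.55),
            (1656, 35, 0.50), (2855, 55, 0.90), (3010, 28, 0.45),
        ), unit_scale=1.3 * s),
        PeakModel("nucleic acids", (
            (785, 24, 0.70), (1095, 24, 0.60), (1340, 35, 0.45),
            (1485, 28, 0.60), (1578, 28, 0.65),
        ), unit_scale=s),
        PeakModel("glycogen", (
            (480, 28, 0.80), (850, 24, 0.50), (940, 24, 0.60),
            (1130, 30, 0.35), (2910, 70, 0.70),
        ), unit_scale=0.9 * s),
        # combined DNA/RNA is one component; cytochrome c is calibrated in
        # ug/mL — per unit mass its resonance signal is ~1000x the others
        PeakModel("cytochrome c", (
            (750, 18, 1.00), (1127, 20, 0.50), (1314, 22, 0.70), (1585, 22, 0.90),
        ), unit_scale=s, concentration_unit="ug/mL"),
    ]


def drug_peak_model(name: str = "drug") -> PeakModel:
    """A xenobiotic reference: fingerprint bands in regions where the
    endogenous library is dark, so the signature is spectrally distinct."""
    return PeakModel(name, (
        (600, 30, 0.70), (660, 24, 0.50), (1180, 30, 0.70), (1730, 30, 1.00),
    ), unit_scale=1.0, concentration_unit="a.u.")


def metabolite_peak_model(parent: PeakModel | None = None,
                          shift_cm1: float = 30.0) -> PeakModel:
    """The parent drug with its strongest peak shifted by ``shift_cm1``.

    Emulates a metabolic bond/structure change that moves one vibrational
    band; used to exercise parent-vs-deposit spectral comparison.
    """
    parent = parent or drug_peak_model()
    peaks = list(parent.peaks)
    strongest = max(range(len(peaks)), key=lambda k: peaks[k][2])
    c, w, h = peaks[strongest]
    peaks[strongest] = (c + shift_cm1, w, h)
    return PeakModel(parent.name + " metabolite", tuple(peaks),
                     unit_scale=parent.unit_scale,
                     concentration_unit=parent.concentration_unit)


def water_band(axis: WavenumberAxis,
               amplitude: float = DEFAULT_WATER_AMPLITUDE) -> np.ndarray:
    """The liquid-water OH stretch: one broad Gaussian at 3400 cm^-1."""
    return _lineshape(axis.values, 3400.0, 200.0, amplitude, "gaussian")


def blank_spectrum(axis: WavenumberAxis, ramp_height: float = 0.3) -> np.ndarray:
    """Matrix-blank analyte signal (agarose/PBS): weak bands + gentle ramp."""
    w = axis.values
    bands = (_lineshape(w, 890, 30, 0.15, "gaussian")
             + _lineshape(w, 1090, 40, 0.10, "gaussian")
             + _lineshape(w, 2900, 100, 0.08, "gaussian"))
    ramp = ramp_height * (w - w[0]) / (w[-1] - w[0])
    return bands + ramp


def simulate_blank(axis: WavenumberAxis,
                   water_amplitude: float = DEFAULT_WATER_AMPLITUDE,
                   dark_offset: float = DEFAULT_DARK_OFFSET) -> Spectrum:
    """A measured matrix-blank spectrum (raw stage, noiseless)."""
    return Spectrum(axis, dark_offset + blank_spectrum(axis) + water_band(axis, water_amplitude),
                    meta={"kind": "matrix blank", "laser_nm": 532.0})


def default_concentration_grid(name: str, n: int = 6) -> np.ndarray:
    lo, hi = DEFAULT_CONCENTRATIONS[name]
    return np.linspace(lo, hi, n)


def simulate_phantom_series(model: PeakModel, concentrations=None,
                            noise_sd: float = 0.0, seed: int | None = None,
                            axis: WavenumberAxis | None = None,
                            water_amplitude: float = DEFAULT_WATER_AMPLITUDE,
                            dark_offset: float = DEFAULT_DARK_OFFSET,
                            ) -> CalibrationSeries:
    """Raw phantom spectra: c x unit spectrum + blank + water + noise.

    Returned spectra are raw-stage; push them through
    :func:`qramanomics.calibration.preprocess_series` before fitting.
    """
    axis = axis or make_axis()
    if concentrations is None:
        concentrations = default_concentration_grid(model.name)
    concentrations = np.asarray(concentrations, dtype=np.float64)
    if np.any(concentrations < 0):
        raise RamanValidationError("phantom concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    unit = make_component_spectrum(model, axis).intensity
    base = dark_offset + blank_spectrum(axis) + water_band(axis, water_amplitude)
    points = []
    for c in concentrations:
        intensity = base + c * unit
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
        points.append((float(c), Spectrum(axis, intensity,
                                          meta={"laser_nm": 532.0, "stage": "raw"})))
    return CalibrationSeries(model.name, model.concentration_unit, points)


def reference_library_from_models(models: list[PeakModel], axis: WavenumberAxis,
                                  config: PreprocessConfig | None = None,
                                  water_amplitude: float = DEFAULT_WATER_AMPLITUDE,
                                  ) -> ReferenceLibrary:
    """The exact unit-scaled library implied by the models, on the cropped grid.

    Scales each unit spectrum by the water-window normalization constant
    the preprocessing pipeline would apply, then crops — the analytic
    counterpart of calibrating on a noiseless phantom series.
    """
    from .preprocess import crop_keep_mask

    config = config or PreprocessConfig()
    base = blank_spectrum(axis) + water_band(axis, water_amplitude)
    ray = axis.window_indices(*config.rayleigh_window, "Rayleigh window")
    shifted = base - base[ray].min()
    widx = axis.window_indices(*config.water_window, "water window")
    norm = shifted[widx].mean()
    keep = crop_keep_mask(axis, config.crop_window, config.silent_mask)
    cropped_axis = WavenumberAxis(axis.values[keep])
    cols = [make_component_spectrum(m, axis).intensity[keep] / norm for m in models]
    return ReferenceLibrary(axis=cropped_axis, names=[m.name for m in models],
                            spectra=np.column_stack(cols),
                            units=[m.concentration_unit for m in models])


# ---------------------------------------------------------------------------
# 3-D ground-truth fields


def _smooth_standard_field(shape, rng, smooth_sigma: float = 1.5) -> np.ndarray:
    """A spatially smooth field normalized to sample mean 0, sample SD 1."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


#: (mean, SD) of the organoid-like concentration fields, in each
#: component's calibration unit; chosen inside the phantom ranges with
#: means a few SDs above zero so clipping at 0 is rare.
DEFAULT_FIELD_STATS = {
    "protein": (100.0, 30.0),
    "DPPC": (30.0, 9.0),
    "POPC": (20.0, 6.0),
    "nucleic acids": (30.0, 8.0),
    "glycogen": (40.0, 12.0),
    "cytochrome c": (50.0, 15.0),
}


def make_organoid_truth(shape: tuple[int, int, int] = (5, 20, 20),
                        seed: int | None = 0,
                        field_stats: dict | None = None,
                        tau_um: float | None = None,
                        noise_sd: float = 0.0,
                        n_deposit_voxels: int = 0,
                        zero_components: tuple[str, ...] = (),
                        ) -> GroundTruth:
    """Smooth random concentration fields for the six-component organoid.

    ``zero_components`` are kept in the truth at exactly 0 everywhere
    (for false-signal studies). Deposit voxels, if requested, are drawn as
    a couple of compact blobs.
    """
    rng = np.random.default_rng(seed)
    stats = field_stats or DEFAULT_FIELD_STATS
    fields = {}
    for name, (mean, sd) in stats.items():
        if name in zero_components:
            fields[name] = np.zeros(shape)
        else:
            fields[name] = np.clip(mean + sd * _smooth_standard_field(shape, rng), 0.0, None)
    deposit_mask = None
    if n_deposit_voxels > 0:
        deposit_mask = _random_deposit_mask(shape, n_deposit_voxels, rng)
    return GroundTruth(fields=fields, deposit_mask=deposit_mask, tau_um=tau_um,
                       noise_sd=noise_sd, seed=seed)


def make_phantom_truth(component: str = "POPC", concentration: float = 40.0,
                       shape: tuple[int, int, int] = (6, 8, 8),
                       tau_um: float | None = None, noise_sd: float = 0.0,
                       seed: int | None = 0) -> GroundTruth:
    """A homogeneous single-component tissue-phantom stack truth.

    Phantoms are spatially uniform by construction, which is what makes
    them usable for depth-dependent signal-interference profiling: any
    plane-to-plane SNR change is attenuation, not composition.
    """
    if concentration < 0:
        raise RamanValidationError("phantom concentration must be non-negative")
    return GroundTruth(fields={component: np.full(shape, float(concentration))},
                       tau_um=tau_um, noise_sd=noise_sd, seed=seed)


def _random_deposit_mask(shape, n_voxels: int, rng) -> np.ndarray:
    """Scatter ``n_voxels`` deposit voxels as a few compact clusters."""
    mask = np.zeros(shape, dtype=bool)
    attempts = 0
    while mask.sum() < n_voxels and attempts < 10_000:
        attempts += 1
        center = tuple(rng.integers(0, s) for s in shape)
        mask[center] = True
        # grow a little blob around the seed
        for _ in range(min(3, n_voxels - int(mask.sum()))):
            offset = tuple(int(np.clip(c + rng.integers(-1, 2), 0, s - 1))
                           for c, s in zip(center, shape))
            if mask.sum() < n_voxels:
                mask[offset] = True
    return mask


def make_two_condition_truths(shape: tuple[int, int, int] = (3, 16, 16),
                              rho_control: float = 0.1, rho_treated: float = 0.7,
                              seed: int | None = 0,
                              ) -> tuple[GroundTruth, GroundTruth]:
    """Control/treated truths whose total-lipid vs protein correlation is set.

    The lipid field is built from the protein field's standardized values
    plus an orthogonalized noise field, so the *sample* correlation of
    total lipid with protein equals the requested value exactly before
    clipping (clipping at 0 is rare by construction). The drug effect is a
    pure co-localization change: marginal means and SDs are identical in
    the two conditions.
    """
    rng = np.random.default_rng(seed)
    truths = []
    for rho in (rho_control, rho_treated):
        p = _smooth_standard_field(shape, rng)
        e = _smooth_standard_field(shape, rng)
        # orthogonalize and re-standardize so the sample correlation is exact
        e = e - (e.ravel() @ p.ravel()) / (p.ravel() @ p.ravel()) * p
        e = (e - e.mean()) / e.std()
        lz = rho * p + math.sqrt(1.0 - rho**2) * e
        lz = (lz - lz.mean()) / lz.std()
        pm, ps = DEFAULT_FIELD_STATS["protein"]
        protein = np.clip(pm + ps * p, 0.0, None)
        lm, ls = 50.0, 15.0  # total lipid mean/SD, mg/mL
        total_lipid = np.clip(lm + ls * lz, 0.0, None)
        fields = {
            "protein": protein,
            "DPPC": 0.55 * total_lipid,
            "POPC": 0.45 * total_lipid,
        }
        for name in ("nucleic acids", "glycogen", "cytochrome c"):
            mean, sd = DEFAULT_FIELD_STATS[name]
            fields[name] = np.clip(mean + sd * _smooth_standard_field(shape, rng), 0.0, None)
        truths.append(GroundTruth(fields=fields, seed=seed))
    return truths[0], truths[1]


def simulate_organoid_stack(truth: GroundTruth,
                            models: list[PeakModel] | None = None,
                            axis: WavenumberAxis | None = None,
                            voxel_pitch: tuple[float, float, float] = DEFAULT_VOXEL_PITCH,
                            water_amplitude: float = DEFAULT_WATER_AMPLITUDE,
                            dark_offset: float = DEFAULT_DARK_OFFSET,
                            drug_model: PeakModel | None = None,
                            drug_amplitude: float = 0.0,
                            ) -> HyperspectralStack:
    """Render a raw hyperspectral stack from ground truth.

    Per voxel: ``raw = dark + a(z) * (sum_k c_k s_k + blank + water
    [+ drug at deposit voxels]) + noise`` with ``a(z) = exp(-z dz / tau)``.
    Analyte, blank and water attenuate together (shared optical path); the
    dark current and detector noise do not.
    """
    models = models or default_peak_models()
    axis = axis or make_axis()
    model_names = {m.name for m in models}
    missing = set(truth.fields) - model_names
    if missing:
        raise RamanValidationError(f"truth has fields with no peak model: {sorted(missing)}")
    nz, ny, nx = truth.shape
    m = len(axis)
    rng = np.random.default_rng(truth.seed)

    signal = np.zeros((nz, ny, nx, m))
    for model in models:
        if model.name not in truth.fields:
            continue
        unit = make_component_spectrum(model, axis).intensity
        signal += truth.fields[model.name][..., None] * unit[None, None, None, :]
    signal += (blank_spectrum(axis) + water_band(axis, water_amplitude))[None, None, None, :]

    if drug_amplitude > 0:
        if truth.deposit_mask is None:
            raise RamanValidationError("drug_amplitude > 0 requires a deposit mask in truth")
        drug = make_component_spectrum(drug_model or drug_peak_model(), axis).intensity
        drug = drug / drug.max()
        signal[truth.deposit_mask] += drug_amplitude * drug

    if truth.tau_um is not None:
        dz = voxel_pitch[0]
        atten = np.exp(-np.arange(nz) * dz / truth.tau_um)
        signal *= atten[:, None, None, None]

    raw = dark_offset + signal
    if truth.noise_sd > 0:
        raw = raw + rng.normal(0.0, truth.noise_sd, size=raw.shape)
    return HyperspectralStack(axis=axis, intensities=raw, voxel_pitch=voxel_pitch,
                              stage="raw", meta={"laser_nm": 532.0})


def noise_sd_for_snr(noiseless_stack: HyperspectralStack, target_snr: float,
                     config: PreprocessConfig | None = None) -> float:
    """Raw-noise SD giving the requested mean voxel SNR.

    SNR per voxel is signal-window max over silent-region SD, so for white
    detector noise of SD sigma the mean SNR is mean(max_signal)/sigma.
    """
    config = config or PreprocessConfig()
    if target_snr <= 0:
        raise RamanValidationError("target SNR must be positive")
    idx = noiseless_stack.axis.window_indices(*config.snr_signal_window, "SNR signal window")
    window = noiseless_stack.intensities[..., idx]
    # window min stands in for the smooth background under the CH band
    sig = (window - window.min(axis=-1, keepdims=True)).max(axis=-1)
    return float(sig.mean() / target_snr)


def simulate_snr_labeled_stack(shape: tuple[int, int, int] = (5, 5, 5),
                               n_below: int = 37, seed: int | None = 0,
                               config: PreprocessConfig | None = None,
                               noise_scale: float = 0.05,
                               ) -> tuple[HyperspectralStack, np.ndarray]:
    """A preprocessed-stage stack with exactly labeled sub-/supra-SNR voxels.

    Each voxel gets a deterministic alternating +-sigma pattern in the
    silent noise window (its sample SD is then known in closed form) and a
    single signal-window channel at 1.5x (supra) or 0.5x (sub) the
    threshold ``snr_factor x SD``. Returns (stack, expected keep mask).
    """
    config = config or PreprocessConfig()
    axis = make_axis()
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    n_total = nz * ny * nx
    if not 0 <= n_below <= n_total:
        raise RamanValidationError(f"n_below must be within [0, {n_total}]")
    noise_idx = axis.window_indices(*config.snr_noise_window, "SNR noise window")
    sig_idx = axis.window_indices(*config.snr_signal_window, "SNR signal window")

    pattern = noise_scale * np.where(np.arange(noise_idx.size) % 2 == 0, 1.0, -1.0)
    sd = float(pattern.std(ddof=1))

    below = np.zeros(n_total, dtype=bool)
    below[rng.choice(n_total, size=n_below, replace=False)] = True
    data = np.zeros((n_total, len(axis)))
    data[:, noise_idx] = pattern
    margin = np.where(below, 0.5, 1.5)
    data[:, sig_idx[sig_idx.size // 2]] = margin * config.snr_factor * sd
    stack = HyperspectralStack(axis=axis, intensities=data.reshape(nz, ny, nx, -1),
                               voxel_pitch=DEFAULT_VOXEL_PITCH, stage="preprocessed",
                               meta={"laser_nm": 532.0})
    return stack, (~below).reshape(shape)


def inject_cosmic_rays(stack: HyperspectralStack, rate: float = 0.025,
                       amplitude_range: tuple[float, float] = (5.0, 50.0),
                       seed: int | None = 0, n_spikes: int | None = None,
                       ) -> tuple[HyperspectralStack, list[tuple[int, int, int, int, float]]]:
    """Add cosmic-ray spikes at logged positions; returns (stack, log).

    ``rate`` is the Poisson mean of spikes per spectrum (``n_spikes``
    instead requests an exact total); amplitudes are uniform in
    ``amplitude_range`` x the spectrum's max intensity (cosmic events dwarf
    the Raman signal). Spikes landing within one despiking window of an
    already-placed spike in the same spectrum are re-drawn so every logged
    spike is an isolated single-channel event. The log holds
    ``(z, y, x, channel, added_amplitude)`` per spike.
    """
    if rate < 0:
        raise RamanValidationError("spike rate must be >= 0")
    rng = np.random.default_rng(seed)
    data = stack.intensities.copy().astype(np.float64)
    nz, ny, nx, m = data.shape
    log: list[tuple[int, int, int, int, float]] = []
    placed_by_voxel: dict[tuple[int, int, int], list[int]] = {}

    if n_spikes is not None:
        targets = []
        while len(targets) < n_spikes:
            z, y, x = (int(rng.integers(0, s)) for s in (nz, ny, nx))
            ch = int(rng.integers(0, m))
            if any(abs(ch - p) <= 9 for p in placed_by_voxel.get((z, y, x), [])):
                continue
            placed_by_voxel.setdefault((z, y, x), []).append(ch)
            targets.append((z, y, x, ch))
    else:
        targets = []
        counts = rng.poisson(rate, size=(nz, ny, nx))
        for z, y, x in np.argwhere(counts > 0):
            for _ in range(counts[z, y, x]):
                ch = int(rng.integers(0, m))
                if any(abs(ch - p) <= 9 for p in placed_by_voxel.get((z, y, x), [])):
                    continue
                placed_by_voxel.setdefault((z, y, x), []).append(ch)
                targets.append((int(z), int(y), int(x), ch))

    for z, y, x, ch in targets:
        amp = float(rng.uniform(*amplitude_range) * max(data[z, y, x].max(), 1e-12))
        data[z, y, x, ch] += amp
        log.append((z, y, x, ch, amp))
    out = HyperspectralStack(axis=stack.axis, intensities=data,
                             voxel_pitch=stack.voxel_pitch, stage=stack.stage,
                             meta={**stack.meta, "cosmic_rays_injected": len(log)},
                             invalid_mask=stack.invalid_mask)
    return out, log
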