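"""Core in-memory containers for Raman hyperspectral data.

All spatial arrays are indexed ``(z, y, x)`` with z index 0 at the specimen
surface (shallowest plane); spectral intensities occupy the trailing axis.
Cross-spectrum arithmetic requires identical wavenumber axes — there is no
implicit interpolation anywhere in the package (see
:func:`qramanomics.preprocess.resample_spectrum` for the explicit one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RamanValidationError",
    "AxisMismatchError",
    "FormatError",
    "NormalizationError",
    "StageError",
    "STAGES",
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralStack",
    "ReferenceLibrary",
    "ConcentrationMap",
]


class RamanValidationError(ValueError):
    """An input violates a structural invariant (shape, monotonicity, range)."""


class AxisMismatchError(RamanValidationError):
    """Two objects that must share a wavenumber axis do not."""


class FormatError(RamanValidationError):
    """An on-disk container is missing a required dataset or attribute."""


class NormalizationError(RamanValidationError):
    """A spectrum cannot be normalized (e.g. non-positive water-band mean)."""


class StageError(RamanValidationError):
    """An operation received a stack at the wrong processing stage."""


#: Allowed processing stages, in forward order.
STAGES = ("raw", "preprocessed", "cropped")


def _as_float_array(values, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != ndim:
        raise RamanValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing grid of Raman shifts in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "wavenumber axis", 1)
        if arr.size < 2:
            raise RamanValidationError("wavenumber axis needs at least 2 channels")
        if not np.all(np.isfinite(arr)):
            raise RamanValidationError("wavenumber axis contains non-finite values")
        if not np.all(np.diff(arr) > 0):
            raise RamanValidationError("wavenumber axis must be strictly increasing")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels inside the closed interval [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)

    def window_indices(self, lo: float, hi: float, what: str = "window") -> np.ndarray:
        """Indices of channels in [lo, hi]; error when the window misses the axis."""
        idx = np.nonzero(self.window_mask(lo, hi))[0]
        if idx.size == 0:
            raise RamanValidationError(
                f"{what} [{lo}, {hi}] cm^-1 contains no channel of axis spanning "
                f"[{self.values[0]:.1f}, {self.values[-1]:.1f}] cm^-1"
            )
        return idx

    def matches(self, other: "WavenumberAxis") -> bool:
        return self.values.shape == other.values.shape and np.array_equal(
            self.values, other.values
        )

    def require_match(self, other: "WavenumberAxis", context: str = "operation") -> None:
        if not self.matches(other):
            raise AxisMismatchError(
                f"{context}: wavenumber axes differ "
                f"({len(self)} vs {len(other)} channels); resample explicitly first"
            )


@dataclass
class Spectrum:
    """One Raman spectrum on a wavenumber grid.

    ``meta`` carries free-form provenance (laser wavelength, integration
    time, processing flags such as ``blank_subtracted``).
    """

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = _as_float_array(self.intensity, "intensity", 1)
        if arr.size != len(self.axis):
            raise RamanValidationError(
                f"intensity length {arr.size} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise RamanValidationError("spectrum intensities must be finite")
        self.intensity = arr

    def replace(self, intensity: np.ndarray | None = None, axis: WavenumberAxis | None = None,
                **meta_updates) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return Spectrum(
            axis=axis if axis is not None else self.axis,
            intensity=self.intensity if intensity is None else intensity,
            meta=new_meta,
        )


@dataclass
class HyperspectralStack:
    """A 3-D confocal Raman scan: per-voxel spectra on a shared axis.

    ``intensities`` has shape ``(nz, ny, nx, m)``; ``voxel_pitch`` is
    ``(dz, dy, dx)`` in micrometres. ``invalid_mask`` (optional, ``(nz, ny,
    nx)`` boolean) marks voxels that failed a preprocessing step; they are
    kept in the array, never dropped.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    voxel_pitch: tuple[float, float, float]
    stage: str = "raw"
    meta: dict = field(default_factory=dict)
    invalid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 4:
            raise RamanValidationError(
                f"stack intensities must be (nz, ny, nx, m), got shape {arr.shape}"
            )
        if arr.shape[-1] != len(self.axis):
            raise RamanValidationError(
                f"stack channel count {arr.shape[-1]} does not match axis length {len(self.axis)}"
            )
        pitch = tuple(float(p) for p in self.voxel_pitch)
        if len(pitch) != 3 or any(p <= 0 for p in pitch):
            raise RamanValidationError(f"voxel_pitch must be 3 positive floats, got {pitch}")
        if self.stage not in STAGES:
            raise RamanValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.invalid_mask is not None:
            mask = np.asarray(self.invalid_mask, dtype=bool)
            if mask.shape != arr.shape[:3]:
                raise RamanValidationError("invalid_mask shape must match the spatial grid")
            self.invalid_mask = mask
        self.intensities = arr
        self.voxel_pitch = pitch

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.spatial_shape))

    def require_stage(self, stage: str, operation: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"{operation} requires a stage={stage!r} stack, got stage={self.stage!r}"
            )

    def advance_stage(self, new_stage: str) -> None:
        """Move to a later stage; backwards transitions are refused."""
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move stack backwards from {self.stage!r} to {new_stage!r}")
        self.stage = new_stage

    def voxel_spectrum(self, z: int, y: int, x: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[z, y, x].astype(np.float64, copy=True),
                        meta=dict(self.meta))


@dataclass
class ReferenceLibrary:
    """Unit-scaled endmember spectra: the calibration matrix X.

    Column k is the spectrum produced by 1 unit of component k
    (``units[k]``, e.g. a.u. per 1 mg/mL), so an unmixing coefficient reads
    directly in that component's concentration unit.
    """

    axis: WavenumberAxis
    names: list[str]
    spectra: np.ndarray  # (m, n), column per component
    units: list[str]

    def __post_init__(self) -> None:
        mat = _as_float_array(self.spectra, "library spectra", 2)
        if mat.shape[0] != len(self.axis):
            raise RamanValidationError(
                f"library row count {mat.shape[0]} does not match axis length {len(self.axis)}"
            )
        self.names = [str(n) for n in self.names]
        self.units = [str(u) for u in self.units]
        if mat.shape[1] != len(self.names) or len(self.names) != len(self.units):
            raise RamanValidationError("names, units and spectrum columns must align")
        if len(self.names) < 1:
            raise RamanValidationError("library needs at least one component")
        if len(set(self.names)) != len(self.names):
            raise RamanValidationError(f"duplicate component names in {self.names}")
        if np.any(mat < 0):
            raise RamanValidationError("library spectra must be non-negative")
        self.spectra = mat

    @property
    def n_components(self) -> int:
        return len(self.names)

    @property
    def matrix(self) -> np.ndarray:
        """The m x n calibration matrix X."""
        return self.spectra

    def component_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}; library has {self.names}") from None

    def component_spectrum(self, name: str) -> Spectrum:
        k = self.component_index(name)
        return Spectrum(self.axis, self.spectra[:, k].copy(), meta={"unit": self.units[k]})


@dataclass
class ConcentrationMap:
    """Per-voxel, per-component concentrations (the stacked beta-hat).

    ``values`` has shape ``(nz, ny, nx, n)``; voxels outside ``valid_mask``
    are NaN in every component and in ``residual_norm``.
    """

    component_names: list[str]
    component_units: list[str]
    values: np.ndarray
    residual_norm: np.ndarray
    valid_mask: np.ndarray
    voxel_pitch: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 4:
            raise RamanValidationError("map values must be (nz, ny, nx, n)")
        if vals.shape[-1] != len(self.component_names):
            raise RamanValidationError("map component axis does not match component_names")
        if len(self.component_names) != len(self.component_units):
            raise RamanValidationError("component_names and component_units must align")
        mask = np.asarray(self.valid_mask, dtype=bool)
        res = np.asarray(self.residual_norm, dtype=np.float64)
        if mask.shape != vals.shape[:3] or res.shape != vals.shape[:3]:
            raise RamanValidationError("valid_mask/residual_norm must match the spatial grid")
        # enforce the NaN-outside-mask convention at construction
        vals = vals.copy()
        res = res.copy()
        vals[~mask] = np.nan
        res[~mask] = np.nan
        if np.any(res[mask] < 0):
            raise RamanValidationError("residual_norm must be non-negative on valid voxels")
        pitch = tuple(float(p) for p in self.voxel_pitch)
        if len(pitch) != 3 or any(p <= 0 for p in pitch):
            raise RamanValidationError(f"voxel_pitch must be 3 positive floats, got {pitch}")
        self.values = vals
        self.residual_norm = res
        self.valid_mask = mask
        self.voxel_pitch = pitch

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def component_index(self, name: str) -> int:
        try:
            return self.component_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown component {name!r}; map has {self.component_names}"
            ) from None

    def component_values(self, name: str) -> np.ndarray:
        """The (nz, ny, nx) concentration field of one component."""
        return self.values[..., self.component_index(name)]

    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_pitch
        return dz * dy * dx
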