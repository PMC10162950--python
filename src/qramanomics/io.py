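"""Readers and writers for the open on-disk containers.

Stacks and concentration maps live in HDF5; reference libraries are plain
CSV (first column ``wavenumber_cm1``, then one column per component named
``"<name>[<unit>]"``); configs are JSON. Intensities are stored in their
in-memory dtype so that a write/read cycle is bit-exact.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    ConcentrationMap,
    FormatError,
    HyperspectralStack,
    RamanValidationError,
    ReferenceLibrary,
    WavenumberAxis,
)

__all__ = [
    "read_stack",
    "write_stack",
    "read_reference_library",
    "write_reference_library",
    "read_concentration_map",
    "write_concentration_map",
]

_META_ATTR = "meta_json"


def _require(group: h5py.File, name: str, path) -> h5py.Dataset:
    if name not in group:
        raise FormatError(f"{path}: container is missing required dataset '{name}'")
    return group[name]


def _require_attr(group, name: str, path):
    if name not in group.attrs:
        raise FormatError(f"{path}: container is missing required attribute '{name}'")
    return group.attrs[name]


def write_stack(stack: HyperspectralStack, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("wavenumbers", data=stack.axis.values)
        f.create_dataset("intensities", data=stack.intensities)
        f.attrs["voxel_pitch_um"] = np.asarray(stack.voxel_pitch, dtype=np.float64)
        f.attrs["stage"] = stack.stage
        f.attrs["laser_nm"] = float(stack.meta.get("laser_nm", np.nan))
        f.attrs[_META_ATTR] = json.dumps(stack.meta, default=str)
        if stack.invalid_mask is not None:
            f.create_dataset("invalid_mask", data=stack.invalid_mask)


def read_stack(path) -> HyperspectralStack:
    path = Path(path)
    with h5py.File(path, "r") as f:
        axis = WavenumberAxis(_require(f, "wavenumbers", path)[...])
        intensities = _require(f, "intensities", path)[...]
        pitch = tuple(float(p) for p in _require_attr(f, "voxel_pitch_um", path))
        stage = str(_require_attr(f, "stage", path))
        meta = json.loads(f.attrs.get(_META_ATTR, "{}"))
        invalid = f["invalid_mask"][...] if "invalid_mask" in f else None
    return HyperspectralStack(
        axis=axis, intensities=intensities, voxel_pitch=pitch, stage=stage,
        meta=meta, invalid_mask=invalid,
    )


_COLUMN_RE = re.compile(r"^(?P<name>.+?)\s*\[(?P<unit>[^\]]+)\]$")


def write_reference_library(library: ReferenceLibrary, path) -> None:
    path = Path(path)
    data = {"wavenumber_cm1": library.axis.values}
    for k, (name, unit) in enumerate(zip(library.names, library.units)):
        data[f"{name}[{unit}]"] = library.spectra[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def read_reference_library(path) -> ReferenceLibrary:
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    if "wavenumber_cm1" not in table.columns:
        raise FormatError(f"{path}: first column must be 'wavenumber_cm1'")
    names, units, columns = [], [], []
    for col in table.columns:
        if col == "wavenumber_cm1":
            continue
        m = _COLUMN_RE.match(col)
        if m is None:
            raise FormatError(
                f"{path}: component column {col!r} must be named '<name>[<unit>]'"
            )
        names.append(m.group("name"))
        units.append(m.group("unit"))
        columns.append(table[col].to_numpy(dtype=np.float64))
    if len(set(names)) != len(names):
        raise RamanValidationError(f"{path}: duplicate component names {names}")
    if not columns:
        raise FormatError(f"{path}: no component columns found")
    axis = WavenumberAxis(table["wavenumber_cm1"].to_numpy(dtype=np.float64))
    return ReferenceLibrary(axis=axis, names=names, spectra=np.column_stack(columns),
                            units=units)


def write_concentration_map(cmap: ConcentrationMap, path) -> None:
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=cmap.values)
            f.create_dataset("residual_norm", data=cmap.residual_norm)
            f.create_dataset("valid_mask", data=cmap.valid_mask)
            f.attrs["component_names"] = [str(n) for n in cmap.component_names]
            f.attrs["component_units"] = [str(u) for u in cmap.component_units]
            f.attrs["voxel_pitch_um"] = np.asarray(cmap.voxel_pitch, dtype=np.float64)
            f.attrs[_META_ATTR] = json.dumps(cmap.meta, default=str)
    except OSError as exc:
        raise OSError(f"failed to write concentration map to {path}: {exc}") from exc


def read_concentration_map(path) -> ConcentrationMap:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = _require(f, "values", path)[...]
        residual = _require(f, "residual_norm", path)[...]
        mask = _require(f, "valid_mask", path)[...].astype(bool)
        names = [str(n) for n in _require_attr(f, "component_names", path)]
        units = [str(u) for u in _require_attr(f, "component_units", path)]
        pitch = tuple(float(p) for p in _require_attr(f, "voxel_pitch_um", path))
        meta = json.loads(f.attrs.get(_META_ATTR, "{}"))
    return ConcentrationMap(
        component_names=names, component_units=units, values=values,
        residual_norm=residual, valid_mask=mask, voxel_pitch=pitch, meta=meta,
    )
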