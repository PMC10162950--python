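"""Phenotype readouts derived from concentration maps.

Co-localization is quantified as the Pearson correlation of two
components' concentrations across valid voxels (literal linear
correlation, not rank-based): r > 0 means the pair tends to occupy the
same voxels, r < 0 mutually exclusive localization. Drug effects are read
as the entry-wise absolute difference between a treated and a control
correlation matrix. Frequency-distribution ("waterfall") data are 2-D
joint histograms of one component against protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConcentrationMap, RamanValidationError

__all__ = [
    "ColocalizationMatrix",
    "JointHistogram",
    "pearson_colocalization",
    "colocalization_difference",
    "joint_histogram",
    "specimen_summary",
    "waterfall_plot",
]


@dataclass
class ColocalizationMatrix:
    component_names: list[str]
    r: np.ndarray       # (n, n) Pearson correlations
    n_voxels: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=np.float64)
        n = len(self.component_names)
        if r.shape != (n, n):
            raise RamanValidationError("correlation matrix shape must match component count")
        self.r = r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.component_names,
                            columns=self.component_names)


@dataclass
class JointHistogram:
    x_component: str
    y_component: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (len(x_edges)-1, len(y_edges)-1) integers


def pearson_colocalization(cmap: ConcentrationMap,
                           components: list[str] | None = None) -> ColocalizationMatrix:
    """Pairwise Pearson correlation of components over valid voxels.

    For each pair, voxels NaN in either component are dropped. A
    zero-variance component yields a NaN row/column (with a warning)
    except on its own diagonal, which stays 1 when the component has any
    finite voxel.
    """
    names = components or list(cmap.component_names)
    cols = [cmap.component_values(n)[cmap.valid_mask] for n in names]
    n_valid = cmap.n_valid
    if n_valid < 2:
        raise RamanValidationError("co-localization needs >= 2 valid voxels")
    n = len(names)
    r = np.full((n, n), np.nan)
    flagged = set()
    for i in range(n):
        for j in range(i, n):
            xi, xj = cols[i], cols[j]
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 2:
                continue
            a, b = xi[ok], xj[ok]
            sa, sb = a.std(), b.std()
            if i == j:
                r[i, i] = 1.0 if sa >= 0 else np.nan
                continue
            if sa == 0 or sb == 0:
                for k, s in ((i, sa), (j, sb)):
                    if s == 0 and names[k] not in flagged:
                        flagged.add(names[k])
                        warnings.warn(
                            f"component {names[k]!r} has zero variance; its "
                            "correlations are undefined", stacklevel=2)
                continue
            rij = float(np.corrcoef(a, b)[0, 1])
            r[i, j] = r[j, i] = np.clip(rij, -1.0, 1.0)
    return ColocalizationMatrix(component_names=list(names), r=r, n_voxels=n_valid)


def colocalization_difference(treated: ColocalizationMatrix,
                              control: ColocalizationMatrix) -> np.ndarray:
    """Entry-wise |r_treated - r_control| (the drug-effect heatmap)."""
    if treated.component_names != control.component_names:
        raise RamanValidationError(
            f"component mismatch: {treated.component_names} vs {control.component_names}"
        )
    return np.abs(treated.r - control.r)


def joint_histogram(cmap: ConcentrationMap, x_component: str, y_component: str,
                    x_edges: np.ndarray, y_edges: np.ndarray) -> JointHistogram:
    """2-D frequency distribution of two components over valid voxels.

    Out-of-range voxels are clipped into the first/last bin so that the
    counts always sum to the number of valid voxels contributing finite
    values in both components.
    """
    x_edges = np.asarray(x_edges, dtype=np.float64)
    y_edges = np.asarray(y_edges, dtype=np.float64)
    for name, e in (("x_edges", x_edges), ("y_edges", y_edges)):
        if e.ndim != 1 or e.size < 2 or not np.all(np.diff(e) > 0):
            raise RamanValidationError(f"{name} must be a strictly increasing 1-D array")
    x = cmap.component_values(x_component)[cmap.valid_mask]
    y = cmap.component_values(y_component)[cmap.valid_mask]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    # clip into the covered range; np.histogram2d's last bin is closed on the
    # right, so clipping to the final edge lands in the end bin
    x = np.clip(x, x_edges[0], x_edges[-1])
    y = np.clip(y, y_edges[0], y_edges[-1])
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    return JointHistogram(x_component=x_component, y_component=y_component,
                          x_edges=x_edges, y_edges=y_edges,
                          counts=counts.astype(np.int64))


def specimen_summary(cmap: ConcentrationMap) -> pd.DataFrame:
    """Per-component summary statistics over valid voxels.

    Columns: mean, median, p95 (in the component's unit), n_valid, and the
    specimen volume covered by valid voxels in um^3.
    """
    if cmap.n_valid == 0:
        raise RamanValidationError("map has no valid voxels to summarize")
    volume = cmap.n_valid * cmap.voxel_volume_um3()
    rows = []
    for name, unit in zip(cmap.component_names, cmap.component_units):
        vals = cmap.component_values(name)[cmap.valid_mask]
        vals = vals[np.isfinite(vals)]
        rows.append({
            "component": name, "unit": unit,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "median": float(np.median(vals)) if vals.size else np.nan,
            "p95": float(np.percentile(vals, 95)) if vals.size else np.nan,
            "n_valid": int(cmap.n_valid),
            "volume_um3": float(volume),
        })
    return pd.DataFrame(rows).set_index("component")


def waterfall_plot(hist: JointHistogram, ax=None, log_counts: bool = True):
    """Render a joint histogram as the conventional frequency-distribution map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    counts = hist.counts.T.astype(float)
    if log_counts:
        counts = np.log10(counts + 1.0)
    mesh = ax.pcolormesh(hist.x_edges, hist.y_edges, counts, cmap="viridis")
    ax.set_xlabel(hist.x_component)
    ax.set_ylabel(hist.y_component)
    ax.figure.colorbar(mesh, ax=ax,
                       label="log10(voxel count + 1)" if log_counts else "voxel count")
    return ax
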