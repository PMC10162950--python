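"""Constrained linear-combination unmixing of preprocessed spectra.

The model is y = X beta + e per voxel, with X the unit-scaled calibration
matrix: beta-hat estimated by least squares, by default under a
non-negativity constraint (active-set NNLS), maps each voxel spectrum to
absolute concentrations in the components' calibration units.

Columns of X are internally normalized to unit l2 norm and the
coefficients back-scaled: cytochrome c's resonance-enhanced column is about
a thousand-fold stronger per unit mass than the other biomolecules, which
makes the raw-unit matrix badly conditioned. The normalization is exactly
equivalent (a diagonal reparametrization) and is asserted as such in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import (
    AxisMismatchError,
    ConcentrationMap,
    HyperspectralStack,
    RamanValidationError,
    ReferenceLibrary,
    Spectrum,
)

__all__ = [
    "MixingResult",
    "BayesResult",
    "ols_unmix",
    "nnls_unmix",
    "bayes_unmix",
    "unmix_stack",
    "TOTAL_LIPID",
    "DEFAULT_LIPID_COMPONENTS",
]

#: Name of the derived summed-lipid channel appended by :func:`unmix_stack`.
TOTAL_LIPID = "total lipid"

#: Lipid-class component names summed into the derived channel by default.
DEFAULT_LIPID_COMPONENTS = ("DPPC", "POPC")


@dataclass
class MixingResult:
    """One voxel's unmixing solution beta-hat and its residual e = y - X beta."""

    beta: np.ndarray
    residual: np.ndarray
    residual_norm: float
    method: str
    condition_number: float
    active_set: np.ndarray  # boolean, beta_k participating (> 0 for NNLS)


@dataclass
class BayesResult:
    """Posterior summary of non-negative mixing coefficients."""

    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray   # 2.5th percentile
    upper: np.ndarray   # 97.5th percentile
    n_draws: int


def _design(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, ReferenceLibrary):
        names = list(X.names)
        mat = X.matrix
        if isinstance(y, Spectrum):
            X.axis.require_match(y.axis, "unmixing")
    else:
        mat = np.asarray(X, dtype=np.float64)
        names = [f"component_{k}" for k in range(mat.shape[1])]
    yv = y.intensity if isinstance(y, Spectrum) else np.asarray(y, dtype=np.float64)
    if mat.ndim != 2:
        raise RamanValidationError("X must be a 2-D matrix (m channels x n components)")
    if yv.ndim != 1 or yv.size != mat.shape[0]:
        raise RamanValidationError(
            f"spectrum length {yv.size} does not match X row count {mat.shape[0]}"
        )
    if not (np.all(np.isfinite(mat)) and np.all(np.isfinite(yv))):
        raise RamanValidationError("unmixing inputs must be finite")
    return mat, yv, names


def _normalize_columns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(mat, axis=0)
    if np.any(norms == 0):
        raise RamanValidationError("X contains an all-zero column")
    return mat / norms, norms


def ols_unmix(X, y) -> MixingResult:
    """Unconstrained least squares via a QR/SVD factorization.

    Solves the normal equations implicitly (never forming (X^T X)^-1) and
    checks that the residual is orthogonal to the column space.
    """
    mat, yv, names = _design(X, y)
    m, n = mat.shape
    if m < n:
        raise RamanValidationError(f"underdetermined system: {m} channels < {n} components")
    matn, norms = _normalize_columns(mat)
    rank = np.linalg.matrix_rank(matn)
    if rank < n:
        # name the offending columns: those whose projection onto the span of
        # the preceding ones leaves almost nothing
        q, r = np.linalg.qr(matn)
        bad = [names[k] for k in range(n) if abs(r[k, k]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise RamanValidationError(
            f"X is rank-deficient (rank {rank} < {n}); collinear columns: {bad or names}"
        )
    coef, *_ = np.linalg.lstsq(matn, yv, rcond=None)
    beta = coef / norms
    residual = yv - mat @ beta
    return MixingResult(
        beta=beta, residual=residual, residual_norm=float(np.linalg.norm(residual)),
        method="ols", condition_number=float(np.linalg.cond(matn)),
        active_set=np.ones(n, dtype=bool),
    )


def nnls_unmix(X, y) -> MixingResult:
    """Least squares with beta >= 0 (Lawson-Hanson active set)."""
    mat, yv, _ = _design(X, y)
    matn, norms = _normalize_columns(mat)
    coef, _ = optimize.nnls(matn, yv)
    beta = coef / norms
    residual = yv - mat @ beta
    return MixingResult(
        beta=beta, residual=residual, residual_norm=float(np.linalg.norm(residual)),
        method="nnls", condition_number=float(np.linalg.cond(matn)),
        active_set=beta > 0,
    )


def bayes_unmix(X, y, noise_sd: float, prior_sd: float, n_draws: int = 10_000,
                seed: int | None = None) -> BayesResult:
    """Posterior of beta under a Gaussian likelihood and a truncated prior.

    Model: y ~ N(X beta, noise_sd^2 I) with independent half-Gaussian priors
    beta_k ~ N(0, prior_sd^2) truncated at 0. The Gaussian part is conjugate
    (closed-form mean and covariance); the truncation to the non-negative
    orthant is handled by sampling — batched rejection from the untruncated
    posterior, falling back to a coordinate-wise Gibbs sampler when the
    acceptance rate is too low. Interval endpoints are non-negative by
    construction.

    This operation is an explicit interpretation of "Bayesian model
    fitting" for confidence assessment: no specific prior family or
    software is canonical, so the simplest conjugate choice is used.
    """
    if noise_sd <= 0 or prior_sd <= 0:
        raise RamanValidationError("noise_sd and prior_sd must be positive")
    mat, yv, _ = _design(X, y)
    n = mat.shape[1]
    rng = np.random.default_rng(seed)

    precision = mat.T @ mat / noise_sd**2 + np.eye(n) / prior_sd**2
    cov = np.linalg.inv(precision)
    mean = cov @ (mat.T @ yv) / noise_sd**2
    chol = np.linalg.cholesky(cov)

    draws = np.empty((0, n))
    for _ in range(50):  # batched rejection
        batch = mean + rng.standard_normal((max(n_draws, 1000), n)) @ chol.T
        accepted = batch[np.all(batch >= 0, axis=1)]
        draws = np.vstack([draws, accepted])
        if draws.shape[0] >= n_draws:
            draws = draws[:n_draws]
            break
    else:
        draws = _gibbs_truncated(mean, cov, n_draws, rng)

    return BayesResult(
        mean=draws.mean(axis=0), sd=draws.std(axis=0, ddof=1),
        lower=np.percentile(draws, 2.5, axis=0),
        upper=np.percentile(draws, 97.5, axis=0),
        n_draws=draws.shape[0],
    )


def _gibbs_truncated(mean: np.ndarray, cov: np.ndarray, n_draws: int,
                     rng: np.random.Generator, burn_in: int = 200) -> np.ndarray:
    """Coordinate-wise Gibbs sampling of N(mean, cov) truncated to beta >= 0."""
    from scipy import stats

    n = mean.size
    precision = np.linalg.inv(cov)
    x = np.clip(mean, 1e-12, None)
    out = np.empty((n_draws, n))
    for it in range(burn_in + n_draws):
        for k in range(n):
            # conditional of coordinate k given the rest is univariate normal
            cond_var = 1.0 / precision[k, k]
            others = np.delete(np.arange(n), k)
            cond_mean = mean[k] - cond_var * precision[k, others] @ (x[others] - mean[others])
            a = (0.0 - cond_mean) / np.sqrt(cond_var)
            x[k] = stats.truncnorm.rvs(a, np.inf, loc=cond_mean,
                                       scale=np.sqrt(cond_var), random_state=rng)
        if it >= burn_in:
            out[it - burn_in] = x
    return out


def unmix_stack(stack: HyperspectralStack, library: ReferenceLibrary,
                method: str = "nnls", mask: np.ndarray | None = None,
                lipid_components: tuple[str, ...] | None = DEFAULT_LIPID_COMPONENTS,
                ) -> ConcentrationMap:
    """Unmix every valid voxel of a preprocessed, cropped stack.

    ``mask`` is the SNR filter mask (True = keep); it is intersected with
    the stack's own validity. Masked/invalid voxels are NaN in every
    component. A derived channel summing the configured lipid-class
    components is appended as ``"total lipid"`` when those components are
    all present.
    """
    stack.axis.require_match(library.axis, "stack unmixing")
    if method not in ("ols", "nnls"):
        raise RamanValidationError(f"method must be 'ols' or 'nnls', got {method!r}")
    solver = ols_unmix if method == "ols" else nnls_unmix

    nz, ny, nx = stack.spatial_shape
    valid = np.ones((nz, ny, nx), dtype=bool)
    if mask is None:
        mask = stack.meta.get("snr_mask")
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if stack.invalid_mask is not None:
        valid &= ~stack.invalid_mask
    valid &= np.isfinite(stack.intensities).all(axis=-1)

    n = library.n_components
    values = np.full((nz, ny, nx, n), np.nan)
    residual_norm = np.full((nz, ny, nx), np.nan)

    mat = library.matrix
    matn, norms = _normalize_columns(mat)
    flat = stack.intensities.reshape(-1, len(stack.axis))
    vflat = valid.reshape(-1)
    beta_flat = values.reshape(-1, n)
    res_flat = residual_norm.reshape(-1)
    if method == "ols":
        # one shared factorization for the whole stack
        idx = np.nonzero(vflat)[0]
        if idx.size:
            coef, *_ = np.linalg.lstsq(matn, flat[idx].T, rcond=None)
            beta = (coef.T / norms)
            beta_flat[idx] = beta
            res_flat[idx] = np.linalg.norm(flat[idx] - beta @ mat.T, axis=1)
    else:
        for i in np.nonzero(vflat)[0]:
            coef, rn = optimize.nnls(matn, flat[i])
            beta_flat[i] = coef / norms
            res_flat[i] = rn

    names = list(library.names)
    units = list(library.units)
    if lipid_components and all(c in names for c in lipid_components):
        lipid_idx = [names.index(c) for c in lipid_components]
        total = values[..., lipid_idx].sum(axis=-1, keepdims=True)
        values = np.concatenate([values, total], axis=-1)
        names.append(TOTAL_LIPID)
        units.append(units[lipid_idx[0]])

    return ConcentrationMap(
        component_names=names, component_units=units, values=values,
        residual_norm=residual_norm, valid_mask=valid,
        voxel_pitch=stack.voxel_pitch,
        meta={"method": method, "lipid_components": list(lipid_components or [])},
    )
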