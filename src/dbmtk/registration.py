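"""Diffeomorphic SVF registration (desk-scale, deterministic).

A classical multiresolution optimizer in the log-domain demons family:
the transformation is parameterized by a stationary velocity field,
exponentiated with scaling and squaring, and updated with a
Gaussian-smoothed (fluid-like) demons force that descends the
sum-of-squared-differences data term.  Step length comes from a
backtracking line search on the data term, so the scheme has no free
step-size parameter and is bit-deterministic for fixed settings.

The module also ingests externally computed SVFs (e.g. from a trained
registration network) stored as 4-D NIfTI with the vector component on
the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, zoom

from .fields import (
    FieldValidationError,
    LabelVolume,
    ScalarVolume,
    VelocityField,
    integrate_svf,
    warp,
)

__all__ = ["RegistrationSettings", "RegistrationResult", "register_svf",
           "load_external_svf"]


@dataclass(frozen=True)
class RegistrationSettings:
    """Optimizer knobs; all resolutions refer to the full-resolution grid."""

    levels: tuple = (4, 2, 1)          # downsampling factors, coarse→fine
    iterations: tuple = (100, 60, 30)  # cap per level
    fluid_sigma: float = 1.5           # Gaussian sigma (voxels) on the update
    squaring_steps: int = 6
    initial_step: float = 2.0          # voxels, line-search start
    line_search_halvings: int = 4
    max_failed_iterations: int = 5     # consecutive non-improving iterations
    mask_dilation: int = 3             # voxels, for masked SSD support


@dataclass
class RegistrationResult:
    svf: VelocityField
    similarity_trace: list = field(default_factory=list)
    converged: bool = True
    settings: RegistrationSettings = field(default_factory=RegistrationSettings)


def _ssd(a: np.ndarray, b: np.ndarray, weight: np.ndarray | None) -> float:
    d = a - b
    if weight is not None:
        d = d * weight
    return float(np.sum(d * d))


def _demons_force(
    fixed: np.ndarray, warped: np.ndarray, weight: np.ndarray | None
) -> np.ndarray:
    """Normalized demons update toward lower SSD, shape (X, Y, Z, 3)."""
    diff = warped - fixed
    grads = np.stack(np.gradient(warped), axis=-1)
    gnorm2 = np.sum(grads ** 2, axis=-1)
    denom = gnorm2 + diff ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(denom > 1e-12, diff / denom, 0.0)
    force = -scale[..., None] * grads
    if weight is not None:
        force = force * weight[..., None]
    return force


def _resample_volume(data: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return data
    return zoom(data, factor, order=1, mode="nearest", grid_mode=True)


def _resample_svf_to(v: np.ndarray, target_shape: tuple) -> np.ndarray:
    """Resample a velocity array to a new grid, rescaling the vectors."""
    if v.shape[:3] == tuple(target_shape):
        return v
    factors = [t / s for t, s in zip(target_shape, v.shape[:3])]
    out = np.stack(
        [zoom(v[..., c], factors, order=1, mode="nearest", grid_mode=True)
         * factors[c] for c in range(3)],
        axis=-1,
    )
    return out


def register_svf(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    settings: RegistrationSettings | None = None,
    mask: LabelVolume | None = None,
) -> RegistrationResult:
    """Estimate the moving→fixed SVF by multiresolution demons descent.

    When ``mask`` is given, the data term and the output field are
    restricted to the dilated foreground (any nonzero label), which
    suppresses background-driven spurious deformation.
    """
    if fixed.shape != moving.shape:
        raise FieldValidationError(
            f"register_svf: shape mismatch {fixed.shape} vs {moving.shape}"
        )
    settings = settings or RegistrationSettings()
    full_shape = fixed.shape
    weight_full = None
    if mask is not None:
        if mask.shape != full_shape:
            raise FieldValidationError(
                f"mask shape {mask.shape} vs image {full_shape}"
            )
        weight_full = binary_dilation(
            mask.data != 0, iterations=settings.mask_dilation
        ).astype(np.float64)

    v = None
    trace: list[float] = []
    converged = True
    for level, factor in enumerate(settings.levels):
        scale = 1.0 / factor
        f_lvl = _resample_volume(fixed.data, scale)
        m_lvl = _resample_volume(moving.data, scale)
        w_lvl = None
        if weight_full is not None:
            w_lvl = (_resample_volume(weight_full, scale) > 0.5).astype(np.float64)
        if v is None:
            v = np.zeros(f_lvl.shape + (3,))
        else:
            v = _resample_svf_to(v, f_lvl.shape)
        sigma = settings.fluid_sigma * scale if scale < 1 else settings.fluid_sigma

        def energy(v_arr: np.ndarray) -> tuple[float, np.ndarray]:
            phi = integrate_svf(
                VelocityField(v_arr), steps=settings.squaring_steps
            )
            warped = warp(ScalarVolume(m_lvl), phi).data
            return _ssd(warped, f_lvl, w_lvl), warped

        current, warped = energy(v)
        trace.append(current)
        level_start = current
        failed = 0
        improved_any = False
        for _ in range(settings.iterations[level]):
            force = _demons_force(f_lvl, warped, w_lvl)
            force = np.stack(
                [gaussian_filter(force[..., c], sigma) for c in range(3)],
                axis=-1,
            )
            fmax = np.max(np.abs(force))
            if fmax < 1e-12:
                break
            step = settings.initial_step / fmax
            improved = False
            for _ in range(settings.line_search_halvings + 1):
                cand = v + step * force
                e_cand, w_cand = energy(cand)
                if e_cand < current:
                    v, current, warped = cand, e_cand, w_cand
                    improved = True
                    break
                step *= 0.5
            trace.append(current)
            if improved:
                failed = 0
                improved_any = True
            else:
                failed += 1
                if failed >= settings.max_failed_iterations:
                    # stalled: the line search can no longer lower the
                    # data term; keep the best iterate
                    break
        if not improved_any and current > level_start:
            converged = False

    v = _resample_svf_to(v, full_shape)
    if weight_full is not None:
        v = v * weight_full[..., None]
    return RegistrationResult(
        svf=VelocityField(v, fixed.affine),
        similarity_trace=trace,
        converged=converged,
        settings=settings,
    )


def load_external_svf(path, expected_shape: tuple | None = None) -> VelocityField:
    """Load and validate a 4-D NIfTI SVF (last axis = 3 components)."""
    v = VelocityField.load(path)
    if expected_shape is not None and v.spatial_shape != tuple(expected_shape):
        raise FieldValidationError(
            f"{path}: SVF grid {v.spatial_shape} does not match working grid "
            f"{tuple(expected_shape)}"
        )
    return v
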