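"""Voxel-wise aging-score / disease-score decomposition and aggregation.

Given the subject-to-template SVF ``v_subject`` and the one-year
normal-aging SVF ``v0``, every voxel's deformation vector is split into
the component parallel to normal aging and the orthogonal remainder:

    AS  = <v_subject, v0> / ||v0||^2      (years; signed)
    ADS = ||v_subject - AS * v0||         (voxels; non-negative)

AS measures how many years of normal aging the local deformation is
worth (negative = younger-looking than the reference); ADS is the
magnitude of the deformation that normal aging cannot explain.

Voxels where ``||v0||`` is tiny produce wildly amplified AS values, so a
quantile-based outlier rejection on ``||v0||`` precedes regional
averaging; the operating quantile is chosen per region by maximizing the
R^2 of the AS-versus-age fit in the cognitively normal group over the
grid 0, 0.1, ..., 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import VelocityField

__all__ = [
    "DEFAULT_EPS",
    "DEFAULT_QUANTILE_GRID",
    "ScoreMap",
    "ScoreRecord",
    "QuantileSelection",
    "decompose_voxelwise",
    "reject_outliers",
    "aggregate_region",
    "select_quantile",
]

#: Guard against division blow-ups at ||v0|| ~ 0; the quantile threshold
#: is the real outlier defence.
DEFAULT_EPS = 1e-8

DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.0, 1.0, 0.1), 10))

GROUPS = ("CN", "CDR0", "CDR0.5", "CDR1", "CDR2")


@dataclass
class ScoreMap:
    """Voxel-wise AS/ADS with the validity mask they are defined on."""

    as_map: np.ndarray     # years, signed; NaN where invalid
    ads_map: np.ndarray    # residual magnitude (voxels); NaN where invalid
    valid_mask: np.ndarray

    def __post_init__(self):
        if not (self.as_map.shape == self.ads_map.shape == self.valid_mask.shape):
            raise ValueError("ScoreMap component shapes differ")

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid_mask))


@dataclass(frozen=True)
class ScoreRecord:
    """One (scan, region) row of the cohort score table."""

    subject_id: str
    age: float
    group: str
    region: str
    AS: float
    ADS: float
    quantile: float
    n_voxels: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.n_voxels <= 0:
            raise ValueError("ScoreRecord requires n_voxels > 0")


@dataclass
class QuantileSelection:
    """R^2 sweep over the outlier-rejection quantile grid."""

    quantile_grid: list = field(default_factory=list)
    r2_per_quantile: list = field(default_factory=list)
    n_voxels_per_quantile: list = field(default_factory=list)
    chosen_quantile: float = 0.0


def decompose_voxelwise(
    v_subject: VelocityField, v0: VelocityField, eps: float = DEFAULT_EPS
) -> ScoreMap:
    """Project the subject SVF onto v0 voxel-by-voxel.

    Voxels with ``||v0|| <= eps`` are marked invalid and carry NaN; their
    disposal is the outlier-rejection stage's job.
    """
    if v_subject.spatial_shape != v0.spatial_shape:
        raise ValueError(
            f"grid mismatch: subject {v_subject.spatial_shape} vs "
            f"v0 {v0.spatial_shape}"
        )
    if eps <= 0:
        raise ValueError("eps must be positive")
    v0_sq = np.sum(v0.data ** 2, axis=-1)
    valid = np.sqrt(v0_sq) > eps
    inner = np.sum(v_subject.data * v0.data, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        as_map = np.where(valid, inner / v0_sq, np.nan)
    residual = v_subject.data - as_map[..., None] * v0.data
    ads_map = np.where(valid, np.linalg.norm(residual, axis=-1), np.nan)
    return ScoreMap(as_map=as_map, ads_map=ads_map, valid_mask=valid)


def reject_outliers(
    score_map: ScoreMap,
    v0: VelocityField,
    region_mask: np.ndarray,
    quantile: float,
) -> ScoreMap:
    """Keep in-region voxels whose ||v0|| reaches the regional quantile.

    The threshold is the linear-interpolation quantile of ``||v0||``
    over the in-region valid voxels; voxels at or above it survive, so
    quantile 0 keeps every valid in-region voxel.
    """
    if not (0.0 <= quantile < 1.0):
        raise ValueError(f"quantile must lie in [0, 1), got {quantile}")
    if region_mask.shape != score_map.valid_mask.shape:
        raise ValueError("region mask shape does not match score map")
    mag = v0.magnitude()
    base = score_map.valid_mask & region_mask.astype(bool)
    if not base.any():
        raise ValueError("no valid voxels in region before thresholding")
    threshold = float(np.quantile(mag[base], quantile))
    keep = base & (mag >= threshold)
    if not keep.any():
        raise ValueError(
            f"outlier rejection at quantile {quantile} retained no voxels"
        )
    return ScoreMap(
        as_map=np.where(keep, score_map.as_map, np.nan),
        ads_map=np.where(keep, score_map.ads_map, np.nan),
        valid_mask=keep,
    )


def aggregate_region(score_map: ScoreMap) -> tuple[float, float, int]:
    """Arithmetic mean of the voxel-wise AS and ADS over valid voxels."""
    n = score_map.n_valid
    if n == 0:
        raise ValueError("cannot aggregate an empty score map")
    mask = score_map.valid_mask
    return (
        float(np.mean(score_map.as_map[mask])),
        float(np.mean(score_map.ads_map[mask])),
        n,
    )


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the simple regression y ~ x (1 - SSE/SST)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    sxx = np.sum(xc ** 2)
    if sxx == 0:
        raise ValueError("degenerate ages: zero variance")
    slope = np.sum(xc * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return 0.0
    return float(1.0 - np.sum(resid ** 2) / sst)


def select_quantile(
    cn_scores_per_quantile: dict,
    ages: np.ndarray,
    n_voxels_per_quantile: dict | None = None,
    grid=DEFAULT_QUANTILE_GRID,
) -> QuantileSelection:
    """Pick the rejection quantile maximizing the CN AS-vs-age R^2.

    ``cn_scores_per_quantile`` maps each grid quantile to the regional
    AS values of the CN scans computed at that quantile (aligned with
    ``ages``).  Ties go to the smallest quantile, which discards the
    least data.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValueError("quantile selection needs at least 3 CN scans")
    if np.var(ages) == 0:
        raise ValueError("degenerate ages: zero variance")
    sel = QuantileSelection()
    for q in grid:
        scores = np.asarray(cn_scores_per_quantile[q], dtype=float)
        if scores.shape != ages.shape:
            raise ValueError(f"scores at quantile {q} misaligned with ages")
        sel.quantile_grid.append(float(q))
        sel.r2_per_quantile.append(_ols_r2(ages, scores))
        if n_voxels_per_quantile is not None:
            sel.n_voxels_per_quantile.append(int(n_voxels_per_quantile[q]))
    r2 = np.asarray(sel.r2_per_quantile)
    # ties (within float slack) go to the smallest quantile
    best = int(np.flatnonzero(r2 >= r2.max() - 1e-12)[0])
    sel.chosen_quantile = sel.quantile_grid[best]
    return sel
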