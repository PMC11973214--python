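"""Dense 3-D scalar/vector field containers and diffeomorphic field algebra.

All spatial mathematics is carried out in 0-based voxel-index coordinates,
with vector components ordered like the array axes.  Physical spacing and
orientation ride along as an affine matrix for I/O only: the pipeline
assumes affinely pre-aligned, isotropically resampled volumes, so voxel
units are the natural working units.

Deformations are stored as *coordinate maps* ``phi`` with ``phi(x)`` the
source-space sample location for target voxel ``x``; composition is then a
pure resampling operation.  A stationary velocity field (SVF) ``v`` is
turned into a diffeomorphism ``exp(v)`` by scaling and squaring: halve the
field ``k`` times, add the identity, and compose the resulting small map
with itself ``k`` times, which approximates the unit-time flow of

    d phi(t)/dt = v(phi(t)),   phi(0) = identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ScalarVolume",
    "LabelVolume",
    "VelocityField",
    "DeformationField",
    "identity_grid",
    "integrate_svf",
    "compose",
    "warp",
    "invert_svf",
    "DEFAULT_SQUARING_STEPS",
]

#: Default number of squaring steps for exp(v); adequate for fields of a
#: few voxels magnitude (halving 7 times puts the scaled field well below
#: the linear-flow regime).
DEFAULT_SQUARING_STEPS = 7


class FieldValidationError(ValueError):
    """Raised when a field fails its structural invariants."""


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise FieldValidationError(f"{what} contains non-finite values")


def _check_same_shape(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise FieldValidationError(
            f"{what}: shape mismatch {a.shape} vs {b.shape}"
        )


@dataclass
class ScalarVolume:
    """A 3-D intensity grid with voxel spacing carried in the affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FieldValidationError(
                f"ScalarVolume requires a 3-D array, got ndim={self.data.ndim}"
            )
        _check_finite(self.data, "ScalarVolume")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise FieldValidationError(
                f"{path}: expected 3-D scalar volume, got ndim={data.ndim}"
            )
        return cls(data, img.affine)


@dataclass
class LabelVolume:
    """A 3-D integer segmentation grid (FreeSurfer/SynthSeg label ids)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FieldValidationError(
                f"LabelVolume requires a 3-D array, got ndim={arr.ndim}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise FieldValidationError("LabelVolume data is not integer-valued")
            arr = rounded
        if arr.min() < 0:
            raise FieldValidationError("LabelVolume labels must be non-negative")
        self.data = arr.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def labels(self) -> np.ndarray:
        return np.unique(self.data)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), img.affine)


@dataclass
class VelocityField:
    """A stationary velocity field: one 3-vector per voxel, in voxels/unit time.

    Stored with shape ``(X, Y, Z, 3)``; the last axis holds the vector
    components in array-axis order.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise FieldValidationError(
                "VelocityField requires shape (X, Y, Z, 3), got "
                f"{self.data.shape}"
            )
        _check_finite(self.data, "VelocityField")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm, shape (X, Y, Z)."""
        return np.linalg.norm(self.data, axis=-1)

    def __neg__(self) -> "VelocityField":
        return replace(self, data=-self.data)

    def __mul__(self, scalar: float) -> "VelocityField":
        return replace(self, data=self.data * float(scalar))

    __rmul__ = __mul__

    def __add__(self, other: "VelocityField") -> "VelocityField":
        _check_same_shape(self.data, other.data, "VelocityField addition")
        return replace(self, data=self.data + other.data)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "VelocityField":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise FieldValidationError(
                f"{path}: expected a 4-D vector field, got ndim={data.ndim}"
            )
        if data.shape[-1] != 3:
            raise FieldValidationError(
                f"{path}: expected 3 vector components on the last axis, "
                f"got {data.shape[-1]}"
            )
        return cls(data, img.affine)

    @classmethod
    def zeros(cls, spatial_shape, affine=None) -> "VelocityField":
        aff = np.eye(4) if affine is None else affine
        return cls(np.zeros(tuple(spatial_shape) + (3,)), aff)


@dataclass
class DeformationField:
    """A coordinate map phi: voxel x -> source coordinate phi(x), in voxels.

    ``data`` has shape ``(X, Y, Z, 3)``.  ``squaring_steps`` records how
    the map was built when it came from :func:`integrate_svf`.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    squaring_steps: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise FieldValidationError(
                "DeformationField requires shape (X, Y, Z, 3), got "
                f"{self.data.shape}"
            )
        _check_finite(self.data, "DeformationField")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def displacement(self) -> np.ndarray:
        """Displacement view u(x) = phi(x) - x, for I/O and diagnostics."""
        return self.data - identity_grid(self.spatial_shape)

    @classmethod
    def identity(cls, spatial_shape, affine=None) -> "DeformationField":
        aff = np.eye(4) if affine is None else affine
        return cls(identity_grid(spatial_shape), aff)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


def identity_grid(spatial_shape) -> np.ndarray:
    """The identity coordinate map, shape (X, Y, Z, 3)."""
    axes = [np.arange(n, dtype=np.float64) for n in spatial_shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _sample_channels(channels: np.ndarray, coords: np.ndarray, order: int) -> np.ndarray:
    """Sample each last-axis channel of ``channels`` at ``coords`` (X,Y,Z,3).

    Out-of-domain coordinates are edge-clamped (``mode='nearest'``).
    """
    pts = np.moveaxis(coords, -1, 0)
    out = np.empty_like(channels)
    for c in range(channels.shape[-1]):
        out[..., c] = map_coordinates(
            channels[..., c], pts, order=order, mode="nearest"
        )
    return out


def integrate_svf(
    v: VelocityField, steps: int = DEFAULT_SQUARING_STEPS
) -> DeformationField:
    """Exponentiate an SVF to a diffeomorphic coordinate map.

    Scaling and squaring: ``phi_0 = id + v / 2**steps`` followed by
    ``steps`` self-compositions, approximating the unit-time flow of the
    stationary ODE.
    """
    if steps < 1:
        raise FieldValidationError(f"steps must be >= 1, got {steps}")
    _check_finite(v.data, "VelocityField")
    grid = identity_grid(v.spatial_shape)
    phi = grid + v.data / (2.0 ** steps)
    for _ in range(steps):
        # phi <- phi o phi, composed via displacement resampling
        disp = phi - grid
        phi = phi + _sample_channels(disp, phi, order=1)
    return DeformationField(phi, v.affine, squaring_steps=steps)


def compose(phi_outer: DeformationField, phi_inner: DeformationField) -> DeformationField:
    """(phi_outer o phi_inner)(x) = phi_outer(phi_inner(x)).

    The outer map's displacement is trilinearly resampled at the inner
    map's coordinates, which keeps translations exact away from edges.
    """
    _check_same_shape(phi_outer.data, phi_inner.data, "compose")
    grid = identity_grid(phi_outer.spatial_shape)
    disp_outer = phi_outer.data - grid
    out = phi_inner.data + _sample_channels(disp_outer, phi_inner.data, order=1)
    return DeformationField(out, phi_outer.affine)


def warp(
    image: ScalarVolume | LabelVolume,
    phi: DeformationField,
    interpolation: str | None = None,
):
    """Resample ``image`` at the phi-mapped coordinates.

    Labels are always resampled with nearest-neighbour; scalar images
    default to trilinear.  Out-of-domain samples take the edge-clamped
    value.
    """
    if image.shape != phi.spatial_shape:
        raise FieldValidationError(
            f"warp: image shape {image.shape} vs deformation grid "
            f"{phi.spatial_shape}"
        )
    is_label = isinstance(image, LabelVolume)
    if interpolation is None:
        interpolation = "nearest" if is_label else "trilinear"
    if is_label and interpolation != "nearest":
        raise FieldValidationError("LabelVolume must be warped with nearest-neighbour")
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    if np.array_equal(phi.data, identity_grid(image.shape)):
        # identity map is the identity operator, bit-exact
        return replace(image, data=image.data.copy())
    pts = np.moveaxis(phi.data, -1, 0)
    out = map_coordinates(
        image.data.astype(np.float64), pts, order=order, mode="nearest"
    )
    if is_label:
        return LabelVolume(np.rint(out).astype(np.int32), image.affine)
    return ScalarVolume(out, image.affine)


def invert_svf(v: VelocityField) -> VelocityField:
    """Inverse deformation generator: in the SVF parameterization,
    ``exp(v)^-1 = exp(-v)``, so inversion is a sign flip."""
    _check_finite(v.data, "VelocityField")
    return -v
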