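"""Entropy focus criterion (EFC): a Shannon-entropy sharpness metric.

For in-mask voxel intensities B_i (i = 1..N),

    EFC   = - sum_i  (B_i / B_max) * ln(B_i / B_max)
    B_max = sqrt(sum_i B_i^2)

so all image energy in a single voxel gives EFC = 0 (perfectly "focused")
and a uniformly gray image attains the maximum, sqrt(N) * ln(sqrt(N)).
The sharper the image, the smaller the EFC.  The normalized variant
divides by that uniform-image maximum, mapping the metric onto [0, 1].
Terms with B_i = 0 contribute 0 (the x*ln(x) limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import LabelVolume, ScalarVolume

__all__ = ["EFCResult", "efc"]


@dataclass(frozen=True)
class EFCResult:
    raw_efc: float        # nats
    normalized_efc: float  # in [0, 1]
    n_voxels: int          # N, in-mask voxel count
    b_max: float           # sqrt of in-mask image energy


def efc(image: ScalarVolume, mask: LabelVolume | None = None) -> EFCResult:
    """Compute raw and normalized EFC over the (masked) image.

    Any nonzero mask label counts as in-mask; with no mask the whole
    volume is used.  Raises ``ValueError`` for negative intensities,
    an empty mask, or an all-zero in-mask image, for which the metric
    is undefined.
    """
    if mask is not None:
        if mask.shape != image.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image {image.shape}"
            )
        values = image.data[mask.data != 0]
    else:
        values = image.data.ravel()
    if values.size == 0:
        raise ValueError("EFC mask selects no voxels")
    if np.any(values < 0):
        raise ValueError("EFC requires non-negative in-mask intensities")
    b_max = float(np.sqrt(np.sum(values.astype(np.float64) ** 2)))
    if b_max == 0.0:
        raise ValueError("EFC undefined for an all-zero in-mask image")
    n = int(values.size)
    ratio = values / b_max
    nz = ratio[ratio > 0]
    raw = float(-np.sum(nz * np.log(nz)))
    # maximum attainable entropy for N voxels: the uniform image, where
    # every ratio is 1/sqrt(N)
    max_entropy = float(np.sqrt(n) * np.log(np.sqrt(n))) if n > 1 else 1.0
    normalized = raw / max_entropy if n > 1 else 0.0
    return EFCResult(raw_efc=raw, normalized_efc=normalized, n_voxels=n, b_max=b_max)
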