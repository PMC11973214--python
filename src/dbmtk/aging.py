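"""Normal-aging velocity field v0 and the regional analysis masks.

The one-year normal-aging field v0 is the SVF aligning a young CN
template to an old one, divided by the age gap in years (linear atrophy
assumption; by default the 60- and 90-year templates, gap 30).  The
young template is the moving image and the old the fixed one, so v0
points along the aging direction.

Regional masks follow the SynthSeg/FreeSurfer label convention:
ventricles {4, 14, 15, 43}, hippocampi & amygdala {17, 53, 18, 54},
whole brain = any nonzero label, and the ventricle *edge map* — the
difference between the old- and young-template ventricle segmentations,
a rim where the homogeneous ventricle interior gives no registration
signal but the boundary does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fields import LabelVolume, VelocityField

__all__ = [
    "VENTRICLE_LABELS",
    "HIPPOCAMPUS_AMYGDALA_LABELS",
    "NormalAgingField",
    "RegionSpec",
    "BUILTIN_REGIONS",
    "build_aging_field",
    "region_mask",
]

VENTRICLE_LABELS = frozenset({4, 14, 15, 43})
HIPPOCAMPUS_AMYGDALA_LABELS = frozenset({17, 53, 18, 54})


@dataclass(frozen=True)
class RegionSpec:
    """A named analysis region: a label set, the whole brain, or the
    derived ventricle-edge map."""

    name: str
    label_ids: frozenset = frozenset()
    edge_map: bool = False
    whole_brain: bool = False

    def __post_init__(self):
        if not (self.edge_map or self.whole_brain) and not self.label_ids:
            raise ValueError(f"region {self.name!r} has an empty label set")


BUILTIN_REGIONS = {
    "whole-brain": RegionSpec("whole-brain", whole_brain=True),
    "ventricles": RegionSpec("ventricles", label_ids=VENTRICLE_LABELS),
    "hippocampi-amygdala": RegionSpec(
        "hippocampi-amygdala", label_ids=HIPPOCAMPUS_AMYGDALA_LABELS
    ),
    "ventricle-edge": RegionSpec("ventricle-edge", edge_map=True),
}


@dataclass
class NormalAgingField:
    """The one-year normal-aging SVF with its source template ages."""

    v0: VelocityField                 # voxels per year
    age_young: float                  # years
    age_old: float                    # years
    reference_age: float = 60.0       # template all subjects register to

    @property
    def age_gap(self) -> float:
        return self.age_old - self.age_young

    def pair_svf(self) -> VelocityField:
        """Re-scale v0 back to the full template-pair SVF."""
        return self.v0 * self.age_gap


def build_aging_field(
    pair_svf: VelocityField,
    age_young: float,
    age_old: float,
    reference_age: float = 60.0,
) -> NormalAgingField:
    """Divide the template-pair SVF by the age gap to get voxels/year."""
    gap = float(age_old) - float(age_young)
    if gap <= 0:
        raise ValueError(
            f"age_old ({age_old}) must exceed age_young ({age_young})"
        )
    v0 = replace(pair_svf, data=pair_svf.data / gap)
    return NormalAgingField(
        v0=v0, age_young=float(age_young), age_old=float(age_old),
        reference_age=float(reference_age),
    )


def _ventricle_mask(seg: LabelVolume) -> np.ndarray:
    return np.isin(seg.data, list(VENTRICLE_LABELS))


def region_mask(
    region: RegionSpec,
    seg_ref: LabelVolume,
    seg_old: LabelVolume | None = None,
    brain_mask: LabelVolume | None = None,
    growth_only: bool = False,
) -> np.ndarray:
    """Boolean voxel mask for an analysis region.

    Labeled regions are intersected with the brain foreground (any
    nonzero voxel of ``brain_mask``, defaulting to ``seg_ref``).  The
    ventricle-edge map is the symmetric difference of the old- and
    reference-template ventricle masks; ``growth_only`` restricts it to
    the enlargement shell old-minus-young.
    """
    if brain_mask is None:
        brain_mask = seg_ref
    if brain_mask.shape != seg_ref.shape:
        raise ValueError(
            f"brain mask shape {brain_mask.shape} vs seg {seg_ref.shape}"
        )
    brain = brain_mask.data != 0

    if region.whole_brain:
        return brain
    if region.edge_map:
        if seg_old is None:
            raise ValueError("ventricle-edge region requires seg_old")
        if seg_old.shape != seg_ref.shape:
            raise ValueError(
                f"seg_old shape {seg_old.shape} vs seg {seg_ref.shape}"
            )
        young_v = _ventricle_mask(seg_ref)
        old_v = _ventricle_mask(seg_old)
        if growth_only:
            return old_v & ~young_v
        return old_v ^ young_v

    wanted = sorted(region.label_ids)
    present = set(np.unique(seg_ref.data).tolist())
    missing = [lab for lab in wanted if lab not in present]
    if len(missing) == len(wanted):
        # a partial label set is tolerated (anatomy varies); a fully
        # absent one is a wrong segmentation
        raise ValueError(
            f"region {region.name!r}: labels {missing} absent from segmentation"
        )
    return np.isin(seg_ref.data, wanted) & brain
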