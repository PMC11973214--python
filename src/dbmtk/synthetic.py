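"""Synthetic brain phantoms, ground-truth aging fields, and cohorts.

Everything downstream of template generation and segmentation can be
exercised without any imaging data: this module builds a smooth
ellipsoidal "brain" phantom with ventricle and hippocampus/amygdala
structures (reusing the FreeSurfer/SynthSeg label ids so the built-in
region definitions apply unchanged), a ground-truth one-year aging
velocity field that enlarges the ventricles and shrinks the medial
temporal blobs, and whole cohorts of subjects with planted aging-score
slopes and group-specific disease offsets.

Direction convention (shared with the rest of the package): an SVF v is
a resampling flow on the reference-template grid, ``subject =
warp(template, exp(v))``.  A subject built with ``s * v_age`` therefore
looks ``s`` years older than the template, and projecting its SVF onto
``v_age`` recovers ``+s``.

The planted disease direction ``w`` is a smooth random field made
voxel-wise orthogonal to ``v_age`` (Gram-Schmidt per voxel) and
unit-normalized on the support of ``v_age``, so a subject SVF

    v = as_true * v_age + ads_true * w + noise

decomposes back to exactly (as_true, ads_true) in the noiseless case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .fields import (
    LabelVolume,
    ScalarVolume,
    VelocityField,
    integrate_svf,
    warp,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SubjectSample",
    "CohortData",
    "make_phantom",
    "make_aging_field",
    "make_disease_direction",
    "make_noise_field",
    "make_subject",
    "make_cohort",
    "save_cohort",
]

# (label, center fraction of grid, radii fraction of grid, intensity)
# Ids follow the FreeSurfer/SynthSeg convention: 2 white matter,
# 3 cortex/gray, 4/43 lateral ventricles, 14/15 third/fourth ventricle,
# 17/53 hippocampi, 18/54 amygdalae.
_BRAIN = dict(center=(0.5, 0.5, 0.5), radii=(0.42, 0.36, 0.36), intensity=0.45, label=3)
_WHITE = dict(center=(0.5, 0.5, 0.5), radii=(0.29, 0.23, 0.23), intensity=0.72, label=2)
_STRUCTURES = (
    dict(name="ventricle-left", label=4, center=(0.5, 0.38, 0.5),
         radii=(0.10, 0.06, 0.16), intensity=0.08, kind="ventricle"),
    dict(name="ventricle-right", label=43, center=(0.5, 0.62, 0.5),
         radii=(0.10, 0.06, 0.16), intensity=0.08, kind="ventricle"),
    dict(name="third-ventricle", label=14, center=(0.58, 0.5, 0.42),
         radii=(0.04, 0.04, 0.04), intensity=0.08, kind="ventricle"),
    dict(name="fourth-ventricle", label=15, center=(0.63, 0.5, 0.33),
         radii=(0.04, 0.04, 0.04), intensity=0.08, kind="ventricle"),
    dict(name="hippocampus-left", label=17, center=(0.67, 0.35, 0.40),
         radii=(0.067, 0.067, 0.067), intensity=0.60, kind="hippocampus"),
    dict(name="hippocampus-right", label=53, center=(0.67, 0.65, 0.40),
         radii=(0.067, 0.067, 0.067), intensity=0.60, kind="hippocampus"),
    dict(name="amygdala-left", label=18, center=(0.71, 0.35, 0.55),
         radii=(0.046, 0.046, 0.046), intensity=0.55, kind="hippocampus"),
    dict(name="amygdala-right", label=54, center=(0.71, 0.65, 0.55),
         radii=(0.046, 0.046, 0.046), intensity=0.55, kind="hippocampus"),
)

GROUP_VOCABULARY = ("CN", "CDR0", "CDR0.5", "CDR1", "CDR2")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of the synthetic brain phantom."""

    shape: tuple = (48, 48, 48)
    smoothing_sigma: float = 0.8   # voxels, on the intensity image only
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for a simulated cohort.

    Defaults emulate an aging/dementia study: cognitively normal scans
    spanning 60-90 years with aging-score slope 1 per year (morphological
    age tracking chronological age), dementia-staged groups carrying
    increasing disease-specific deformation orthogonal to normal aging,
    and smooth SVF noise standing in for registration error.
    """

    n_per_group: dict = dc_field(default_factory=lambda: {
        "CN": 40, "CDR0": 20, "CDR0.5": 20, "CDR1": 15, "CDR2": 4})
    age_range: dict = dc_field(default_factory=lambda: {
        "CN": (60.0, 90.0), "CDR0": (62.0, 88.0), "CDR0.5": (64.0, 90.0),
        "CDR1": (66.0, 90.0), "CDR2": (70.0, 90.0)})
    as_slope: float = 1.0          # planted AS slope, years of AS per year of age
    ads_offsets: dict = dc_field(default_factory=lambda: {
        "CN": 0.0, "CDR0": 0.05, "CDR0.5": 0.10, "CDR1": 0.15, "CDR2": 0.20})
    noise_sigma: float = 0.05      # voxels, std of the smooth SVF noise
    reference_age: float = 60.0
    seed: int = 0


@dataclass
class SubjectSample:
    subject_id: str
    age: float
    group: str
    svf_true: VelocityField
    image: ScalarVolume | None
    as_true: float
    ads_true: float


@dataclass
class CohortData:
    subjects: list
    truth: pd.DataFrame
    spec: CohortSpec


def _ellipsoid_mask(shape, center_frac, radii_frac) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    rho2 = np.zeros(shape)
    for g, n, c, r in zip(grids, shape, center_frac, radii_frac):
        rho2 += ((g - c * n) / (r * n)) ** 2
    return rho2 <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[ScalarVolume, LabelVolume]:
    """Build the template phantom and its segmentation.

    The intensity image is smoothed for realistic soft edges; the label
    image is crisp.  Deterministic for a fixed spec.
    """
    shape = tuple(spec.shape)
    labels = np.zeros(shape, dtype=np.int32)
    intensity = np.zeros(shape, dtype=np.float64)

    brain = _ellipsoid_mask(shape, _BRAIN["center"], _BRAIN["radii"])
    labels[brain] = _BRAIN["label"]
    intensity[brain] = _BRAIN["intensity"]
    white = _ellipsoid_mask(shape, _WHITE["center"], _WHITE["radii"])
    labels[white] = _WHITE["label"]
    intensity[white] = _WHITE["intensity"]

    masks = []
    for s in _STRUCTURES:
        m = _ellipsoid_mask(shape, s["center"], s["radii"])
        if not m.any():
            raise ValueError(f"structure {s['name']} is empty on grid {shape}")
        if not brain[m].all():
            raise ValueError(f"structure {s['name']} extends outside the brain")
        for other_name, other in masks:
            if (m & other).any():
                raise ValueError(
                    f"structures {s['name']} and {other_name} overlap"
                )
        masks.append((s["name"], m))
        labels[m] = s["label"]
        intensity[m] = s["intensity"]

    if spec.smoothing_sigma > 0:
        intensity = gaussian_filter(intensity, spec.smoothing_sigma)
    intensity = np.clip(intensity, 0.0, 1.0)
    return ScalarVolume(intensity), LabelVolume(labels)


def make_aging_field(
    template: ScalarVolume,
    seg: LabelVolume,
    rate: float = 0.04,
    shell_width: float = 0.25,
) -> VelocityField:
    """Ground-truth one-year aging SVF: ventricles enlarge, the
    hippocampus/amygdala blobs shrink.

    ``rate`` is the peak boundary speed in voxels per year;
    ``shell_width`` the Gaussian width of the boundary shell in units of
    normalized ellipsoid radius.  In the resampling convention used here
    (``older = warp(template, exp(dt * v))``) enlargement means the flow
    points *into* the ventricle at its boundary, and shrinkage means it
    points outward at the blob boundary.  The field is exactly zero
    outside the brain and scales linearly with ``rate``.
    """
    if template.shape != seg.shape:
        raise ValueError("template and segmentation shapes differ")
    shape = template.shape
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    v = np.zeros(shape + (3,))
    for s in _STRUCTURES:
        center = np.array([c * n for c, n in zip(s["center"], shape)])
        radii = np.array([r * n for r, n in zip(s["radii"], shape)])
        delta = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
        rho = np.sqrt(np.sum((delta / radii) ** 2, axis=-1))
        dist = np.linalg.norm(delta, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dist[..., None] > 1e-9, delta / dist[..., None], 0.0)
        shell = np.exp(-((rho - 1.0) ** 2) / (2.0 * shell_width ** 2))
        # ventricle growth: sample from inside (flow points inward);
        # hippocampus shrinkage: sample from outside (flow points outward)
        sign = -1.0 if s["kind"] == "ventricle" else 1.0
        v += sign * rate * shell[..., None] * unit
    brain = seg.data != 0
    v *= brain[..., None]
    return VelocityField(v, template.affine)


def make_disease_direction(
    v_age: VelocityField, seed: int = 0, smooth_sigma: float = 3.0,
    eps: float = 1e-8,
) -> VelocityField:
    """A smooth unit field voxel-wise orthogonal to the aging field.

    Built by per-voxel Gram-Schmidt of a smoothed random field against
    ``v_age`` followed by magnitude normalization on the support of
    ``||v_age||``; zero where ``v_age`` vanishes (those voxels are
    invalid for scoring anyway).
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(v_age.data.shape)
    raw = np.stack(
        [gaussian_filter(raw[..., c], smooth_sigma) for c in range(3)], axis=-1
    )
    mag_age = v_age.magnitude()
    support = mag_age > eps
    with np.errstate(invalid="ignore", divide="ignore"):
        v_hat = np.where(support[..., None], v_age.data / mag_age[..., None], 0.0)
    proj = np.sum(raw * v_hat, axis=-1)
    w = raw - proj[..., None] * v_hat
    w_mag = np.linalg.norm(w, axis=-1)
    ok = support & (w_mag > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(ok[..., None], w / w_mag[..., None], 0.0)
    return VelocityField(w, v_age.affine)


def make_noise_field(
    spatial_shape, sigma: float, seed: int, smooth_sigma: float = 2.0
) -> VelocityField:
    """Smooth Gaussian SVF noise (registration-error surrogate):
    smoothed white noise rescaled so each component has std ``sigma``."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(tuple(spatial_shape) + (3,))
    if sigma == 0:
        return VelocityField(np.zeros_like(noise))
    noise = np.stack(
        [gaussian_filter(noise[..., c], smooth_sigma) for c in range(3)], axis=-1
    )
    std = noise.std()
    if std > 0:
        noise *= sigma / std
    return VelocityField(noise)


def make_subject(
    template: ScalarVolume,
    v_age: VelocityField,
    as_true: float,
    ads_true: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    render_image: bool = True,
    disease_direction: VelocityField | None = None,
) -> tuple[ScalarVolume | None, VelocityField]:
    """Synthesize one subject: SVF = as*v_age + ads*w + noise, and the
    correspondingly deformed image."""
    if not np.isfinite(as_true):
        raise ValueError("as_true must be finite")
    if ads_true < 0:
        raise ValueError("ads_true must be non-negative")
    svf = as_true * v_age
    if ads_true > 0:
        w = disease_direction if disease_direction is not None \
            else make_disease_direction(v_age, seed=seed + 104729)
        svf = svf + ads_true * w
    if noise_sigma > 0:
        svf = svf + make_noise_field(v_age.spatial_shape, noise_sigma, seed)
    image = None
    if render_image:
        if np.allclose(svf.data, 0.0):
            image = ScalarVolume(template.data.copy(), template.affine)
        else:
            image = warp(template, integrate_svf(svf))
    return image, svf


def make_cohort(
    spec: CohortSpec,
    template: ScalarVolume,
    seg: LabelVolume,
    v_age: VelocityField,
    render_images: bool = False,
) -> CohortData:
    """Simulate a full cohort with planted AS/ADS structure.

    Ages are drawn uniformly from each group's range; the planted aging
    score is ``as_slope * (age - reference_age)``, and each group adds
    its disease offset along the shared orthogonal direction ``w``.
    Deterministic for a fixed spec seed.
    """
    for g in spec.n_per_group:
        if g not in GROUP_VOCABULARY:
            raise ValueError(f"unknown group {g!r}")
    rng = np.random.default_rng(spec.seed)
    w = make_disease_direction(v_age, seed=spec.seed + 7919)
    subjects: list[SubjectSample] = []
    rows = []
    idx = 0
    for group in GROUP_VOCABULARY:
        n = int(spec.n_per_group.get(group, 0))
        lo, hi = spec.age_range.get(group, (60.0, 90.0))
        ages = rng.uniform(lo, hi, size=n)
        for age in ages:
            sid = f"sub-{idx:04d}"
            as_true = spec.as_slope * (age - spec.reference_age)
            ads_true = float(spec.ads_offsets.get(group, 0.0))
            image, svf = make_subject(
                template, v_age, as_true, ads_true,
                noise_sigma=spec.noise_sigma,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
                render_image=render_images,
                disease_direction=w,
            )
            subjects.append(SubjectSample(
                subject_id=sid, age=float(age), group=group,
                svf_true=svf, image=image,
                as_true=float(as_true), ads_true=ads_true,
            ))
            rows.append(dict(subject_id=sid, age=float(age), group=group,
                             as_true=float(as_true), ads_true=ads_true))
            idx += 1
    truth = pd.DataFrame(
        rows, columns=["subject_id", "age", "group", "as_true", "ads_true"]
    )
    return CohortData(subjects=subjects, truth=truth, spec=spec)


def save_cohort(cohort: CohortData, out_dir) -> Path:
    """Write a cohort to disk: per-subject NIfTI SVFs (and images when
    rendered), a demographics table, and the hidden truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in cohort.subjects:
        sub.svf_true.save(out / f"{sub.subject_id}_svf.nii.gz")
        if sub.image is not None:
            sub.image.save(out / f"{sub.subject_id}_T1w.nii.gz")
    demo = cohort.truth[["subject_id", "age", "group"]]
    demo.to_csv(out / "demographics.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    with open(out / "cohort_spec.json", "w") as fh:
        json.dump(
            {
                "n_per_group": cohort.spec.n_per_group,
                "age_range": {k: list(v) for k, v in cohort.spec.age_range.items()},
                "as_slope": cohort.spec.as_slope,
                "ads_offsets": cohort.spec.ads_offsets,
                "noise_sigma": cohort.spec.noise_sigma,
                "reference_age": cohort.spec.reference_age,
                "seed": cohort.spec.seed,
            },
            fh, indent=2,
        )
    return out
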