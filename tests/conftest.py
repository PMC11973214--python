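import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from dbmtk import (
    VelocityField,
    build_aging_field,
    integrate_svf,
    register_svf,
    warp,
)
from dbmtk.synthetic import CohortSpec, make_aging_field, make_cohort, make_phantom


def smooth_random_svf(shape, max_magnitude, seed, sigma=2.0):
    """A smooth random velocity field with a prescribed max |v|."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(tuple(shape) + (3,))
    v = np.stack([gaussian_filter(v[..., c], sigma) for c in range(3)], axis=-1)
    peak = np.abs(v).max()
    if peak > 0:
        v *= max_magnitude / peak
    return VelocityField(v)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def aging_phantom(phantom):
    template, seg = phantom
    v_age = make_aging_field(template, seg)
    return template, seg, v_age


@pytest.fixture(scope="session")
def phantom_registration(aging_phantom):
    """Self-deformed phantom registration, shared across tests (slow)."""
    template, seg, v_age = aging_phantom
    v_true = 30.0 * v_age  # max |v| ~ 2 voxels
    subject = warp(template, integrate_svf(v_true))
    result = register_svf(subject, template, mask=seg)
    return dict(template=template, seg=seg, v_true=v_true,
                subject=subject, result=result)


@pytest.fixture(scope="session")
def fitted_cohort(aging_phantom):
    """Simulated cohort with planted AS slope 1/yr and staged ADS
    offsets, decomposed with the automatic quantile sweep."""
    from dbmtk import AgingDecomposition

    template, seg, v_age = aging_phantom
    cohort = make_cohort(CohortSpec(seed=1), template, seg, v_age)
    naf = build_aging_field(30.0 * v_age, 60.0, 90.0)
    model = AgingDecomposition.from_cohort(cohort, naf, seg)
    return cohort, model.fit(quantile="auto")
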