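import numpy as np
import pytest

from dbmtk import (
    VelocityField,
    aggregate_region,
    decompose_voxelwise,
    reject_outliers,
    select_quantile,
)
from dbmtk.scores import DEFAULT_QUANTILE_GRID

from conftest import smooth_random_svf

SHAPE = (10, 10, 10)


def brute_force_projection(v_sub: np.ndarray, v0: np.ndarray):
    """Independent per-voxel projection oracle (plain Python loops)."""
    as_o = np.full(v_sub.shape[:3], np.nan)
    ads_o = np.full(v_sub.shape[:3], np.nan)
    for idx in np.ndindex(v_sub.shape[:3]):
        b = v0[idx]
        nb2 = float(b @ b)
        if np.sqrt(nb2) <= 1e-8:
            continue
        a = float(v_sub[idx] @ b) / nb2
        as_o[idx] = a
        ads_o[idx] = float(np.linalg.norm(v_sub[idx] - a * b))
    return as_o, ads_o


@pytest.fixture()
def v0():
    return smooth_random_svf(SHAPE, 1.0, seed=11)


class TestDecompose:
    def test_subject_equals_v0_gives_unit_as_zero_ads(self, v0):
        sm = decompose_voxelwise(v0, v0)
        assert np.allclose(sm.as_map[sm.valid_mask], 1.0)
        assert np.allclose(sm.ads_map[sm.valid_mask], 0.0, atol=1e-12)

    def test_orthogonal_subject_gives_zero_as_full_ads(self):
        v0_data = np.zeros(SHAPE + (3,))
        v0_data[..., 0] = 1.0
        sub = np.zeros(SHAPE + (3,))
        sub[..., 1] = 0.75
        sm = decompose_voxelwise(VelocityField(sub), VelocityField(v0_data))
        assert np.allclose(sm.as_map[sm.valid_mask], 0.0)
        assert np.allclose(sm.ads_map[sm.valid_mask], 0.75)

    def test_random_constructions_match_bruteforce_oracle(self, v0):
        rng = np.random.default_rng(42)
        a = rng.uniform(-2, 2, SHAPE)
        # per-voxel orthogonal direction via Gram-Schmidt of a random field
        r = rng.standard_normal(SHAPE + (3,))
        mag = np.linalg.norm(v0.data, axis=-1, keepdims=True)
        v_hat = np.where(mag > 1e-12, v0.data / mag, 0.0)
        w = r - np.sum(r * v_hat, axis=-1, keepdims=True) * v_hat
        wmag = np.linalg.norm(w, axis=-1, keepdims=True)
        w = np.where(wmag > 1e-12, w / wmag, 0.0)
        d = rng.uniform(0, 1, SHAPE)
        sub = VelocityField(a[..., None] * v0.data + d[..., None] * w)
        sm = decompose_voxelwise(sub, v0)
        as_o, ads_o = brute_force_projection(sub.data, v0.data)
        m = sm.valid_mask
        assert np.allclose(sm.as_map[m], as_o[m], atol=1e-6)
        assert np.allclose(sm.ads_map[m], ads_o[m], atol=1e-6)
        # planted coefficients are recovered where w is truly orthogonal
        ok = m & (wmag[..., 0] > 1e-12)
        assert np.allclose(sm.as_map[ok], a[ok], atol=1e-6)
        assert np.allclose(sm.ads_map[ok], d[ok], atol=1e-6)

    def test_pythagoras_per_voxel(self, v0):
        sub = smooth_random_svf(SHAPE, 1.5, seed=12)
        sm = decompose_voxelwise(sub, v0)
        m = sm.valid_mask
        lhs = np.sum(sub.data ** 2, axis=-1)[m]
        v0n = np.linalg.norm(v0.data, axis=-1)[m]
        rhs = (sm.as_map[m] * v0n) ** 2 + sm.ads_map[m] ** 2
        assert np.allclose(lhs, rhs, rtol=1e-6)

    @pytest.mark.parametrize("alpha", [2.0, -1.5])
    def test_linearity_in_subject_field(self, v0, alpha):
        sub = smooth_random_svf(SHAPE, 1.0, seed=13)
        sm1 = decompose_voxelwise(sub, v0)
        sm2 = decompose_voxelwise(alpha * sub, v0)
        m = sm1.valid_mask
        assert np.allclose(sm2.as_map[m], alpha * sm1.as_map[m], atol=1e-9)
        assert np.allclose(sm2.ads_map[m], abs(alpha) * sm1.ads_map[m],
                           atol=1e-9)

    def test_antiparallel_subject_has_negative_as(self, v0):
        sm = decompose_voxelwise(-0.5 * v0, v0)
        assert np.all(sm.as_map[sm.valid_mask] < 0)

    def test_shape_mismatch_rejected(self, v0):
        with pytest.raises(ValueError):
            decompose_voxelwise(VelocityField.zeros((8, 8, 8)), v0)


class TestRejectOutliers:
    def test_quantile_zero_keeps_all_valid_voxels(self, v0):
        sm = decompose_voxelwise(v0, v0)
        region = np.ones(SHAPE, dtype=bool)
        kept = reject_outliers(sm, v0, region, 0.0)
        assert kept.n_valid == int(np.count_nonzero(sm.valid_mask & region))

    def test_median_threshold_matches_sorting_oracle(self):
        # distinct ||v0|| values by construction
        data = np.zeros(SHAPE + (3,))
        data[..., 0] = (np.arange(np.prod(SHAPE)) + 1).reshape(SHAPE) * 1e-3
        v0 = VelocityField(data)
        sm = decompose_voxelwise(v0, v0)
        region = np.ones(SHAPE, dtype=bool)
        kept = reject_outliers(sm, v0, region, 0.5)
        n = int(np.prod(SHAPE))
        assert kept.n_valid == int(np.ceil(n / 2))
        mags = np.sort(v0.magnitude().ravel())
        oracle_kept = set(np.argsort(v0.magnitude().ravel())[-kept.n_valid:])
        assert kept.n_valid == len(oracle_kept)
        assert v0.magnitude()[kept.valid_mask].min() >= mags[n - kept.n_valid]

    def test_retained_counts_monotone_over_grid(self, v0):
        sm = decompose_voxelwise(smooth_random_svf(SHAPE, 1.0, seed=14), v0)
        region = np.ones(SHAPE, dtype=bool)
        counts = [reject_outliers(sm, v0, region, q).n_valid
                  for q in DEFAULT_QUANTILE_GRID]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_invalid_quantile_and_empty_region(self, v0):
        sm = decompose_voxelwise(v0, v0)
        with pytest.raises(ValueError):
            reject_outliers(sm, v0, np.ones(SHAPE, bool), 1.0)
        with pytest.raises(ValueError):
            reject_outliers(sm, v0, np.zeros(SHAPE, bool), 0.0)


class TestAggregate:
    def test_uniform_and_two_voxel_means(self):
        as_map = np.full(SHAPE, np.nan)
        ads_map = np.full(SHAPE, np.nan)
        valid = np.zeros(SHAPE, bool)
        valid[0, 0, 0] = valid[0, 0, 1] = True
        as_map[valid] = [1.0, 3.0]
        ads_map[valid] = [0.5, 0.5]
        from dbmtk.scores import ScoreMap
        a, d, n = aggregate_region(ScoreMap(as_map, ads_map, valid))
        assert (a, d, n) == (2.0, 0.5, 2)

    def test_matches_recomputation_oracle(self, v0):
        sub = smooth_random_svf(SHAPE, 1.0, seed=15)
        sm = decompose_voxelwise(sub, v0)
        a, d, n = aggregate_region(sm)
        m = sm.valid_mask
        assert a == pytest.approx(sm.as_map[m].sum() / n, rel=1e-12)
        assert d == pytest.approx(sm.ads_map[m].sum() / n, rel=1e-12)


def closed_form_r2(x, y):
    """Simple-regression R^2 = corr(x, y)^2 (closed form, independent)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    c = np.corrcoef(x, y)[0, 1]
    return c * c


class TestSelectQuantile:
    def test_exact_linear_scores_pick_smallest_quantile(self):
        ages = np.linspace(60, 90, 20)
        scores = {q: ages - 60.0 for q in DEFAULT_QUANTILE_GRID}
        sel = select_quantile(scores, ages)
        assert sel.chosen_quantile == 0.0
        assert np.allclose(sel.r2_per_quantile, 1.0)

    def test_r2_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(60, 90, 50)
        scores = {q: (ages - 60) + rng.normal(0, 2 + 10 * q, 50)
                  for q in DEFAULT_QUANTILE_GRID}
        sel = select_quantile(scores, ages)
        for q, r2 in zip(sel.quantile_grid, sel.r2_per_quantile):
            assert r2 == pytest.approx(closed_form_r2(ages, scores[q]),
                                       abs=1e-10)

    def test_noisy_low_magnitude_voxels_push_quantile_up(self, aging_phantom,
                                                         fitted_cohort):
        """In the simulated cohort the SVF noise dominates where ||v0|| is
        small, so the chosen quantile must discard those voxels and beat
        (or match) the keep-everything fit."""
        _, res = fitted_cohort
        sel = res.quantile_selections["whole-brain"]
        assert sel.chosen_quantile > 0.0
        assert max(sel.r2_per_quantile) >= sel.r2_per_quantile[0]

    def test_degenerate_ages_rejected(self):
        scores = {q: np.ones(5) for q in DEFAULT_QUANTILE_GRID}
        with pytest.raises(ValueError):
            select_quantile(scores, np.full(5, 70.0))
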