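import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dbmtk import (
    ancova_adjust,
    cohens_d,
    effect_size_band,
    fit_score_vs_age,
    pairwise_tests,
    significance_band,
)


class TestFitScoreVsAge:
    def test_exact_line(self):
        ages = np.linspace(60, 90, 10)
        fit = fit_score_vs_age(ages, 2.0 * (ages - 60.0))
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_score_has_zero_slope_and_r2(self):
        ages = np.linspace(60, 90, 10)
        fit = fit_score_vs_age(ages, np.full(10, 3.3))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_closed_form(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(60, 90, 100)
        scores = (ages - 60.0) + rng.normal(0, 3.0, 100)
        fit = fit_score_vs_age(ages, scores)
        resid = scores - fit.predict(ages)
        sst = np.sum((scores - scores.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - np.sum(resid ** 2) / sst,
                                              abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_score_vs_age([70, 70, 70], [1, 2, 3])


def make_table(groups, ages, scores):
    return pd.DataFrame({"group": groups, "age": ages, "AS": scores})


class TestAncovaAdjust:
    def test_zero_age_effect_reduces_to_cn_centering(self):
        rng = np.random.default_rng(0)
        groups = ["CN"] * 10 + ["CDR0.5"] * 10
        ages = rng.uniform(60, 90, 20)
        scores = np.where(np.array(groups) == "CN", 1.0, 4.0)
        adj = ancova_adjust(make_table(groups, ages, scores), "AS")
        cn_mean = scores[:10].mean()
        assert np.allclose(adj, scores - cn_mean, atol=1e-9)

    def test_pure_age_confound_vanishes(self):
        """Groups that differ only through age collapse to ~0 after
        adjustment when the score is pure age."""
        rng = np.random.default_rng(1)
        groups = ["CN"] * 30 + ["CDR1"] * 30
        ages = np.concatenate([rng.uniform(60, 75, 30),
                               rng.uniform(75, 90, 30)])
        scores = ages.astype(float)
        tab = make_table(groups, ages, scores)
        adj = ancova_adjust(tab, "AS")
        for g in ("CN", "CDR1"):
            assert abs(adj[np.array(groups) == g].mean()) < 1e-8

    def test_cn_mean_is_exactly_zero(self):
        rng = np.random.default_rng(2)
        groups = rng.choice(["CN", "CDR0", "CDR1"], 60).tolist()
        groups[:2] = ["CN", "CN"]
        ages = rng.uniform(60, 90, 60)
        scores = rng.normal(0, 1, 60) + 0.3 * ages
        adj = ancova_adjust(make_table(groups, ages, scores), "AS")
        assert abs(adj[np.array(groups) == "CN"].mean()) < 1e-10

    def test_missing_cn_group_rejected(self):
        tab = make_table(["CDR1"] * 4, [70, 71, 72, 73], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="CN"):
            ancova_adjust(tab, "AS")


class TestPairwise:
    def test_identical_groups_give_zero_effect(self):
        vals = np.arange(10, dtype=float)
        tab = make_table(["CN"] * 10 + ["CDR0"] * 10, [70.0] * 20,
                         np.concatenate([vals, vals]))
        (res,) = pairwise_tests(tab, score="AS", pairs=[("CN", "CDR0")])
        assert res.cohens_d == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)
        assert res.significance == "ns"

    def test_known_effect_size_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(0.8, 1.0, 200)
        tab = make_table(["CN"] * 200 + ["CDR1"] * 200, [70.0] * 400,
                         np.concatenate([b, a]))
        (res,) = pairwise_tests(tab, score="AS", pairs=[("CN", "CDR1")])
        assert 0.6 <= abs(res.cohens_d) <= 1.0

    def test_bonferroni_never_below_raw_and_capped(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(["CN", "CDR0", "CDR0.5", "CDR1"], 15)
        tab = make_table(groups, [70.0] * 60, rng.normal(0, 1, 60))
        results = pairwise_tests(tab, score="AS")
        assert len(results) == 6
        for r in results:
            assert r.p_corrected >= r.p_raw
            assert r.p_corrected <= 1.0
            assert r.p_corrected == pytest.approx(min(1.0, r.p_raw * 6))

    def test_cohens_d_antisymmetric(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_small_groups_excluded_not_crashed(self):
        rng = np.random.default_rng(6)
        groups = ["CN"] * 20 + ["CDR2"] * 4
        tab = make_table(groups, [70.0] * 24, rng.normal(0, 1, 24))
        notices = []
        results = pairwise_tests(tab, score="AS", log=notices.append)
        assert results == []
        assert any("CDR2" in n for n in notices)

    def test_welch_vs_pooled_flag(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 5, 50)
        tab = make_table(["CN"] * 30 + ["CDR1"] * 50, [70.0] * 80,
                         np.concatenate([a, b]))
        welch = pairwise_tests(tab, score="AS", pairs=[("CN", "CDR1")])[0]
        pooled = pairwise_tests(tab, score="AS", pairs=[("CN", "CDR1")],
                                equal_var=True)[0]
        t_w = sps.ttest_ind(a, b, equal_var=False)
        t_p = sps.ttest_ind(a, b, equal_var=True)
        assert welch.t_statistic == pytest.approx(t_w.statistic)
        assert pooled.t_statistic == pytest.approx(t_p.statistic)

    def test_null_type1_rate_is_calibrated(self):
        """Under the null, the raw-p rejection rate at alpha=0.05 over
        1000 repetitions (n=30/30) must sit near 0.05."""
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, (1000, 30))
        b = rng.normal(0, 1, (1000, 30))
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        # cross-check one repetition through the package's own path
        tab = make_table(["CN"] * 30 + ["CDR0"] * 30, [70.0] * 60,
                         np.concatenate([a[0], b[0]]))
        ours = pairwise_tests(tab, score="AS", pairs=[("CN", "CDR0")])[0]
        assert ours.p_raw == pytest.approx(p[0])
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07


class TestBands:
    @pytest.mark.parametrize("d,band", [
        (-0.40, "medium"), (-0.70, "large"), (-0.95, "very large"),
        (0.35, "medium"), (0.649999, "medium"), (0.65, "large"),
        (0.9, "very large"), (0.0, "none"), (0.349, "none"),
    ])
    def test_effect_size_bands(self, d, band):
        assert effect_size_band(d) == band

    @pytest.mark.parametrize("p,stars", [
        (0.2, "ns"), (0.05, "*"), (0.02, "*"), (0.01, "**"),
        (0.001, "***"), (0.0001, "****"), (1e-6, "****"),
    ])
    def test_significance_legend(self, p, stars):
        assert significance_band(p) == stars

    def test_nonfinite_effect_rejected(self):
        with pytest.raises(ValueError):
            effect_size_band(np.nan)
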