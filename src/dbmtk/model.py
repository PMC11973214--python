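"""Cohort-level aging/disease decomposition as a fit-able model.

:class:`AgingDecomposition` bundles a cohort of subject-to-template
SVFs with the one-year normal-aging field ``v0`` and the regional
analysis masks; :meth:`AgingDecomposition.fit` runs the voxel-wise
projection decomposition, the quantile outlier-rejection sweep (chosen
per region by maximizing the cognitively-normal AS-versus-age R^2), and
regional aggregation.  The returned :class:`AgingDecompositionResults`
carries the per-scan regional score table and exposes the cohort
statistics (age-trend fits, ANCOVA age adjustment, pairwise tests) and
a text ``summary()``.

Typical use::

    model = AgingDecomposition(svfs, ages, groups, v0=aging_field,
                               seg_ref=seg60, seg_old=seg90)
    res = model.fit(quantile="auto")
    print(res.summary())
    res.pairwise_tests(region="ventricles", score="AS")
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort_stats
from .aging import BUILTIN_REGIONS, NormalAgingField, RegionSpec, region_mask
from .fields import LabelVolume, VelocityField
from .scores import (
    DEFAULT_EPS,
    DEFAULT_QUANTILE_GRID,
    QuantileSelection,
    decompose_voxelwise,
    select_quantile,
)

__all__ = ["AgingDecomposition", "AgingDecompositionResults"]


def _quantile_means(values: np.ndarray, order: np.ndarray, counts: list):
    """Mean of ``values`` over the top-``k`` entries for each k in counts,
    where ``order`` sorts the region's ||v0|| ascending."""
    sorted_vals = values[order]
    csum = np.cumsum(sorted_vals[::-1])
    return [csum[k - 1] / k for k in counts]


class AgingDecomposition:
    """Decomposition of cohort deformation into aging and disease parts.

    Parameters
    ----------
    svfs : sequence of VelocityField
        Subject-to-template SVFs, one per scan, on the template grid.
    ages, groups, subject_ids : sequences
        Scan-level demographics aligned with ``svfs``.
    v0 : NormalAgingField or VelocityField
        One-year normal-aging field (voxels/year).
    seg_ref : LabelVolume
        Segmentation of the reference (young) template.
    seg_old : LabelVolume, optional
        Segmentation of the old template; required for the
        ventricle-edge region.
    regions : dict of name -> RegionSpec, optional
        Defaults to the four built-ins (whole brain, ventricles,
        hippocampi & amygdala, ventricle edge — dropped when ``seg_old``
        is missing).
    """

    def __init__(
        self,
        svfs,
        ages,
        groups,
        v0,
        seg_ref: LabelVolume,
        seg_old: LabelVolume | None = None,
        subject_ids=None,
        regions: dict | None = None,
        eps: float = DEFAULT_EPS,
    ):
        self.svfs = list(svfs)
        self.ages = np.asarray(ages, dtype=float)
        self.groups = list(groups)
        if not (len(self.svfs) == len(self.ages) == len(self.groups)):
            raise ValueError("svfs, ages and groups must be aligned")
        if subject_ids is None:
            subject_ids = [f"sub-{i:04d}" for i in range(len(self.svfs))]
        self.subject_ids = list(subject_ids)
        if isinstance(v0, NormalAgingField):
            self.aging_field = v0
            self.v0 = v0.v0
        else:
            self.aging_field = None
            self.v0 = v0
        self.seg_ref = seg_ref
        self.seg_old = seg_old
        if regions is None:
            regions = dict(BUILTIN_REGIONS)
            if seg_old is None:
                regions.pop("ventricle-edge")
        self.regions = regions
        self.eps = eps

    @classmethod
    def from_cohort(cls, cohort, v0, seg_ref, seg_old=None, **kw):
        """Build from a :class:`~dbmtk.synthetic.CohortData`."""
        return cls(
            svfs=[s.svf_true for s in cohort.subjects],
            ages=[s.age for s in cohort.subjects],
            groups=[s.group for s in cohort.subjects],
            subject_ids=[s.subject_id for s in cohort.subjects],
            v0=v0, seg_ref=seg_ref, seg_old=seg_old, **kw,
        )

    def _region_masks(self) -> dict:
        masks = {}
        for name, spec in self.regions.items():
            masks[name] = region_mask(
                spec, self.seg_ref, seg_old=self.seg_old, brain_mask=self.seg_ref
            )
        return masks

    def fit(
        self,
        quantile: float | str = "auto",
        quantile_grid=DEFAULT_QUANTILE_GRID,
    ) -> "AgingDecompositionResults":
        """Decompose every scan and aggregate regional scores.

        ``quantile='auto'`` sweeps the rejection quantile per region and
        keeps the one maximizing the CN AS-vs-age R^2; a float fixes the
        quantile for every region.
        """
        grid = [float(q) for q in quantile_grid]
        v0_mag = self.v0.magnitude()
        masks = self._region_masks()
        cn_idx = [i for i, g in enumerate(self.groups) if g == "CN"]

        region_info = {}
        for name, mask in masks.items():
            base = mask & (v0_mag > self.eps)
            if not base.any():
                raise ValueError(f"region {name!r} has no valid voxels")
            mags = v0_mag[base]
            order = np.argsort(mags, kind="stable")
            counts = []
            for q in grid:
                thr = np.quantile(mags, q)
                counts.append(int(np.count_nonzero(mags >= thr)))
            region_info[name] = dict(base=base, order=order, counts=counts)

        # per-region, per-quantile, per-scan regional means
        as_means = {name: np.empty((len(self.svfs), len(grid)))
                    for name in masks}
        ads_means = {name: np.empty((len(self.svfs), len(grid)))
                     for name in masks}
        for i, svf in enumerate(self.svfs):
            sm = decompose_voxelwise(svf, self.v0, eps=self.eps)
            for name, info in region_info.items():
                as_vals = sm.as_map[info["base"]]
                ads_vals = sm.ads_map[info["base"]]
                as_means[name][i] = _quantile_means(
                    as_vals, info["order"], info["counts"])
                ads_means[name][i] = _quantile_means(
                    ads_vals, info["order"], info["counts"])

        selections: dict[str, QuantileSelection] = {}
        chosen: dict[str, float] = {}
        for name in masks:
            if quantile == "auto":
                if len(cn_idx) < 3:
                    raise ValueError(
                        "quantile='auto' needs at least 3 CN scans")
                per_q = {q: as_means[name][cn_idx, j]
                         for j, q in enumerate(grid)}
                nvox = {q: region_info[name]["counts"][j]
                        for j, q in enumerate(grid)}
                sel = select_quantile(per_q, self.ages[cn_idx],
                                      n_voxels_per_quantile=nvox, grid=grid)
                selections[name] = sel
                chosen[name] = sel.chosen_quantile
            else:
                q = float(quantile)
                if q not in grid:
                    raise ValueError(
                        f"fixed quantile {q} must be on the grid {grid}")
                chosen[name] = q

        rows = []
        for name in masks:
            j = grid.index(chosen[name])
            n_vox = region_info[name]["counts"][j]
            for i in range(len(self.svfs)):
                rows.append(dict(
                    subject_id=self.subject_ids[i],
                    age=self.ages[i],
                    group=self.groups[i],
                    region=name,
                    AS=as_means[name][i, j],
                    ADS=ads_means[name][i, j],
                    quantile=chosen[name],
                    n_voxels=n_vox,
                ))
        scores = pd.DataFrame(rows)
        return AgingDecompositionResults(
            model=self, scores=scores, quantile_selections=selections,
            chosen_quantiles=chosen, quantile_grid=grid,
        )


@dataclass
class AgingDecompositionResults:
    """Fitted regional scores plus the cohort-statistics surface."""

    model: AgingDecomposition
    scores: pd.DataFrame
    quantile_selections: dict
    chosen_quantiles: dict
    quantile_grid: list = field(default_factory=list)

    def region_table(self, region: str) -> pd.DataFrame:
        sub = self.scores[self.scores["region"] == region]
        if sub.empty:
            raise KeyError(f"region {region!r} not in results")
        return sub

    def fit_vs_age(self, region: str, score: str = "AS",
                   group: str | None = "CN") -> cohort_stats.AgeTrendFit:
        """OLS of a regional score on age (CN scans by default)."""
        tab = self.region_table(region)
        if group is not None:
            tab = tab[tab["group"] == group]
        return cohort_stats.fit_score_vs_age(tab["age"], tab[score])

    def ancova_adjusted(self, region: str, score: str = "AS") -> pd.DataFrame:
        """Age-adjusted, CN-centered scores for one region."""
        tab = self.region_table(region).reset_index(drop=True)
        adj = cohort_stats.ancova_adjust(tab, score)
        out = tab[["subject_id", "age", "group", "region"]].copy()
        out[f"{score}_adjusted"] = adj
        return out

    def pairwise_tests(self, region: str, score: str = "AS",
                       adjusted: bool = True, pairs=None, **kw):
        """Bonferroni-corrected independent t-tests between groups."""
        if adjusted:
            tab = self.ancova_adjusted(region, score)
            col = f"{score}_adjusted"
        else:
            tab = self.region_table(region)
            col = score
        return cohort_stats.pairwise_tests(tab, score=col, pairs=pairs, **kw)

    def stats_table(self, scorelist=("AS", "ADS"), adjusted=True) -> pd.DataFrame:
        """All pairwise tests for every region and score, one row each."""
        rows = []
        for region in self.scores["region"].unique():
            for score in scorelist:
                for ps in self.pairwise_tests(region, score, adjusted=adjusted):
                    rows.append(dict(
                        region=region, score=score,
                        group_a=ps.group_a, group_b=ps.group_b,
                        t=ps.t_statistic, p_raw=ps.p_raw,
                        p_corrected=ps.p_corrected, cohens_d=ps.cohens_d,
                        significance=ps.significance,
                        effect_band=ps.effect_band,
                        n_a=ps.n_a, n_b=ps.n_b,
                    ))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Aging/disease deformation decomposition", "=" * 44]
        n_scans = self.scores["subject_id"].nunique()
        lines.append(f"scans: {n_scans}   regions: "
                     f"{', '.join(self.scores['region'].unique())}")
        for region in self.scores["region"].unique():
            q = self.chosen_quantiles[region]
            lines.append(f"\n[{region}]  rejection quantile = {q:.1f}")
            if region in self.quantile_selections:
                sel = self.quantile_selections[region]
                r2s = ", ".join(f"{q_:.1f}:{r:.3f}" for q_, r in
                                zip(sel.quantile_grid, sel.r2_per_quantile))
                lines.append(f"  CN AS~age R^2 sweep: {r2s}")
            try:
                fit = self.fit_vs_age(region, "AS")
                lines.append(
                    f"  CN AS ~ age: slope={fit.slope:+.3f}/yr  "
                    f"R^2={fit.r_squared:.3f}  (n={fit.n})")
            except ValueError:
                pass
            tab = self.region_table(region)
            for g, sub in tab.groupby("group", observed=True):
                lines.append(
                    f"  {g:7s} n={len(sub):3d}  AS={sub['AS'].mean():+7.2f}  "
                    f"ADS={sub['ADS'].mean():.4f}")
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_age_trend(self, region: str, score: str = "AS", ax=None):
        """Scatter of score vs age with the fitted line and 95% CI band."""
        import matplotlib.pyplot as plt

        tab = self.region_table(region)
        cn = tab[tab["group"] == "CN"]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(cn["age"], cn[score], s=12, alpha=0.7)
        grid, mean, lo, hi = cohort_stats.age_trend_confidence_band(
            cn["age"].to_numpy(), cn[score].to_numpy())
        ax.plot(grid, mean, color="red")
        ax.fill_between(grid, lo, hi, color="red", alpha=0.2)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(score)
        ax.set_title(f"{region}: {score} vs age (CN)")
        return ax

    def plot_group_boxes(self, region: str, score: str = "AS",
                         adjusted: bool = True, ax=None):
        """Boxplots of (adjusted) scores per group with significance stars."""
        import matplotlib.pyplot as plt

        if adjusted:
            tab = self.ancova_adjusted(region, score)
            col = f"{score}_adjusted"
        else:
            tab = self.region_table(region)
            col = score
        order = [g for g in ("CN", "CDR0", "CDR0.5", "CDR1", "CDR2")
                 if g in set(tab["group"])]
        data = [tab.loc[tab["group"] == g, col].to_numpy() for g in order]
        if ax is None:
            _, ax = plt.subplots()
        ax.boxplot(data, tick_labels=order)
        tests = cohort_stats.pairwise_tests(tab, score=col)
        ymax = tab[col].max()
        span = tab[col].max() - tab[col].min() or 1.0
        h = 0.06 * span
        for k, ps in enumerate(t for t in tests if t.significance != "ns"):
            i, j = order.index(ps.group_a) + 1, order.index(ps.group_b) + 1
            y = ymax + (k + 1) * h
            ax.plot([i, i, j, j], [y, y + h / 3, y + h / 3, y], color="k", lw=0.8)
            ax.text((i + j) / 2, y + h / 3, ps.significance,
                    ha="center", va="bottom", fontsize=8)
        ax.set_ylabel(col)
        ax.set_title(f"{region}: {score}")
        return ax
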