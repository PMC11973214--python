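"""Group-comparison statistics for regional AS/ADS scores.

Covers the cohort-analysis layer: ordinary least-squares fits of score
versus chronological age (with R^2 and confidence band), ANCOVA-based
age adjustment with CN-mean centering, pairwise independent t-tests
with Bonferroni correction, and Cohen's d with banded effect-size
labels.

Significance bands follow the conventional star legend
(ns: p > 0.05; *: 0.01 < p <= 0.05; **: 0.001 < p <= 0.01;
***: 0.0001 < p <= 0.001; ****: p <= 0.0001) applied to the
Bonferroni-corrected p.  Effect sizes on |d|: medium [0.35, 0.65),
large [0.65, 0.9), very large >= 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "MIN_GROUP_SIZE_FOR_TESTS",
    "AgeTrendFit",
    "PairwiseStats",
    "fit_score_vs_age",
    "ancova_adjust",
    "pairwise_tests",
    "cohens_d",
    "effect_size_band",
    "significance_band",
]

#: Groups smaller than this are excluded from hypothesis testing (in the
#: motivating cohort the moderate-dementia stage had only four scans).
MIN_GROUP_SIZE_FOR_TESTS = 5


@dataclass(frozen=True)
class AgeTrendFit:
    slope: float
    intercept: float
    r_squared: float
    slope_pvalue: float
    n: int

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ages, dtype=float)


@dataclass(frozen=True)
class PairwiseStats:
    group_a: str
    group_b: str
    t_statistic: float
    p_raw: float
    p_corrected: float
    cohens_d: float
    significance: str       # ns / * / ** / *** / ****
    effect_band: str        # none / medium / large / very large
    n_a: int
    n_b: int


def fit_score_vs_age(ages, scores) -> AgeTrendFit:
    """OLS of a regional score on chronological age."""
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if ages.size < 3:
        raise ValueError("age-trend fit needs at least 3 records")
    if np.var(ages) == 0:
        raise ValueError("degenerate design: zero age variance")
    df = pd.DataFrame({"age": ages, "score": scores})
    fit = smf.ols("score ~ age", data=df).fit()
    # a constant score has no variance to explain: define R^2 = 0
    r2 = float(fit.rsquared) if fit.centered_tss > 0 else 0.0
    return AgeTrendFit(
        slope=float(fit.params["age"]),
        intercept=float(fit.params["Intercept"]),
        r_squared=r2,
        slope_pvalue=float(fit.pvalues["age"]),
        n=int(ages.size),
    )


def age_trend_confidence_band(ages, scores, grid=None, alpha: float = 0.05):
    """95% confidence band for the fitted mean line, for plotting."""
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    df = pd.DataFrame({"age": ages, "score": scores})
    fit = smf.ols("score ~ age", data=df).fit()
    if grid is None:
        grid = np.linspace(ages.min(), ages.max(), 100)
    pred = fit.get_prediction(pd.DataFrame({"age": grid}))
    frame = pred.summary_frame(alpha=alpha)
    return grid, frame["mean"].to_numpy(), frame["mean_ci_lower"].to_numpy(), \
        frame["mean_ci_upper"].to_numpy()


def ancova_adjust(table: pd.DataFrame, score: str = "AS") -> pd.Series:
    """Age-adjust a score by ANCOVA and center it on the CN group.

    Fits ``score ~ age + group`` (additive, common slope), removes the
    age effect relative to the mean CN age, then subtracts the CN-group
    mean so cognitively normal scans center at 0.
    """
    required = {"age", "group", score}
    if not required.issubset(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    if "CN" not in set(table["group"]):
        raise ValueError("ANCOVA adjustment requires a CN group")
    counts = table["group"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"every group needs >= 2 rows; too small: {small}")
    df = table[["age", "group"]].copy()
    df["y"] = table[score].astype(float)
    fit = smf.ols("y ~ age + C(group)", data=df).fit()
    beta_age = float(fit.params["age"])
    cn_age = float(df.loc[df["group"] == "CN", "age"].mean())
    adjusted = df["y"] - beta_age * (df["age"] - cn_age)
    adjusted = adjusted - adjusted[df["group"] == "CN"].mean()
    adjusted.name = f"{score}_adjusted"
    return adjusted


def cohens_d(a, b) -> float:
    """Pooled-SD standardized mean difference, sign = mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def significance_band(p: float) -> str:
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def effect_size_band(d: float) -> str:
    """Band |d|: < 0.35 none, [0.35, 0.65) medium, [0.65, 0.9) large,
    >= 0.9 very large."""
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    a = abs(d)
    if a < 0.35:
        return "none"
    if a < 0.65:
        return "medium"
    if a < 0.9:
        return "large"
    return "very large"


def pairwise_tests(
    table: pd.DataFrame,
    score: str = "AS",
    pairs=None,
    equal_var: bool = False,
    min_group_size: int = MIN_GROUP_SIZE_FOR_TESTS,
    log=None,
):
    """Independent t-tests on group pairs with Bonferroni correction.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    classic pooled test).  Groups with fewer than ``min_group_size``
    rows are excluded from testing rather than crashing; exclusions are
    reported through ``log`` when given.
    """
    groups = {g: sub[score].to_numpy(dtype=float)
              for g, sub in table.groupby("group", observed=True)}
    if pairs is None:
        names = [g for g in groups]
        pairs = [(names[i], names[j])
                 for i in range(len(names)) for j in range(i + 1, len(names))]
    tested = []
    for ga, gb in pairs:
        if ga not in groups or gb not in groups:
            raise ValueError(f"pair ({ga}, {gb}): group missing from table")
        if len(groups[ga]) < min_group_size or len(groups[gb]) < min_group_size:
            if log is not None:
                log(f"excluded pair ({ga}, {gb}): group below "
                    f"{min_group_size} scans")
            continue
        tested.append((ga, gb))
    n_comparisons = len(tested)
    results = []
    for ga, gb in tested:
        a, b = groups[ga], groups[gb]
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        p_corr = min(1.0, float(p) * n_comparisons)
        d = cohens_d(a, b)
        results.append(PairwiseStats(
            group_a=ga, group_b=gb,
            t_statistic=float(t), p_raw=float(p), p_corrected=p_corr,
            cohens_d=d,
            significance=significance_band(p_corr),
            effect_band=effect_size_band(d),
            n_a=len(a), n_b=len(b),
        ))
    return results
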