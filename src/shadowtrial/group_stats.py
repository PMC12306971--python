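"""Group-level statistics: Mann-Whitney comparisons with percent-change
effect summaries, a permutation test on dispersion, and the genotype x age
trend analysis.

Conventions
-----------
* Group comparisons use the two-sided Mann-Whitney U test (exact null for
  small tie-free samples, tie-corrected normal approximation otherwise).
* Percent change is computed on group means of per-fly values,
  100 * (mean_mutant - mean_control) / mean_control; a median-based variant
  is available via ``basis="median"``.
* The dispersion statistic is |log(var_A / var_B)| on median-centered
  values (Brown-Forsythe-style centering): scale-free and insensitive to
  location shifts.  The permutation p-value uses the add-one rule
  p = (1 + #{perm >= obs}) / (n_perm + 1), which is valid (conservative)
  at any permutation count.
* The age analysis fits a two-way ANOVA (genotype x age, with interaction)
  on per-fly response proportions, backs it with per-genotype
  Kruskal-Wallis tests, and reports uncorrected adjacent-age Mann-Whitney
  post-hocs with an advisory interpretive threshold of p = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

#: advisory threshold for uncorrected post-hoc p-values
POSTHOC_ALPHA = 0.01


@dataclass
class ComparisonResult:
    metric: str
    group_labels: tuple[str, str]  # (control, test)
    n: tuple[int, int]
    summaries: dict  # per-group mean / median / IQR
    percent_change: float
    direction: str  # 'increase' / 'decrease' / 'none'
    statistic: float
    pvalue: float
    test_name: str = "Mann-Whitney U (two-sided)"


@dataclass
class AgeTrendResult:
    response: str
    anova: pd.DataFrame  # rows genotype / age / interaction / residual
    kruskal_by_genotype: dict
    posthoc: pd.DataFrame  # adjacent-age Mann-Whitney per genotype
    posthoc_alpha: float = POSTHOC_ALPHA


def _summary(x: np.ndarray) -> dict:
    q1, q3 = np.percentile(x, [25, 75])
    return {"mean": float(np.mean(x)), "median": float(np.median(x)),
            "iqr": (float(q1), float(q3))}


def compare_groups(
    control: np.ndarray,
    test: np.ndarray,
    metric: str = "metric",
    labels: tuple[str, str] = ("control", "test"),
    basis: str = "mean",
) -> ComparisonResult:
    """Two-sided Mann-Whitney comparison of per-fly metric values.

    ``control`` is the reference group for the percent-change summary.
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(control) < 3 or len(test) < 3:
        raise ParameterError("each group needs at least 3 values")
    pooled = np.concatenate([control, test])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; p set to 1", stacklevel=2)
        stat, p = float(len(control) * len(test) / 2), 1.0
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(control), len(test)) <= 8 and not has_ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(control, test, alternative="two-sided",
                                 method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    center = np.mean if basis == "mean" else np.median
    c0, c1 = float(center(control)), float(center(test))
    if c0 == 0:
        pct = np.nan
        direction = "undefined"
    else:
        pct = 100.0 * (c1 - c0) / c0
        direction = "increase" if pct > 0 else ("decrease" if pct < 0 else "none")
    return ComparisonResult(
        metric=metric, group_labels=labels, n=(len(control), len(test)),
        summaries={labels[0]: _summary(control), labels[1]: _summary(test)},
        percent_change=float(pct), direction=direction,
        statistic=stat, pvalue=p,
    )


def dispersion_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """|log variance ratio| after median-centering each group."""
    a = np.asarray(a, dtype=float) - np.median(a)
    b = np.asarray(b, dtype=float) - np.median(b)
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 0.0
    if va == 0 or vb == 0:
        return np.inf
    return abs(float(np.log(va / vb)))


def dispersion_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test for unequal dispersion between two groups.

    Values are median-centered within their own group first, then group
    labels are randomly reassigned among the centered residuals.  Returns
    (pvalue, observed_statistic).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("each group needs at least 3 values")
    obs = dispersion_statistic(a, b)
    if obs == 0.0 and np.var(a) == 0 and np.var(b) == 0:
        return 1.0, 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resid = np.concatenate([a - np.median(a), b - np.median(b)])
    na, n = len(a), len(resid)
    # vectorized permutations: each row is one random relabeling
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = resid[perm]
    pa, pb = shuffled[:, :na], shuffled[:, na:]
    va = np.var(pa - np.median(pa, axis=1, keepdims=True), axis=1, ddof=1)
    vb = np.var(pb - np.median(pb, axis=1, keepdims=True), axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_stat = np.abs(np.log(va / vb))
    perm_stat = np.nan_to_num(perm_stat, nan=0.0, posinf=np.inf)
    p = (1.0 + np.sum(perm_stat >= obs)) / (n_perm + 1.0)
    return float(p), float(obs)


def age_trend_analysis(
    per_fly: pd.DataFrame,
    response: str,
    value_col: str = "proportion",
) -> AgeTrendResult:
    """Genotype x age analysis of one response type's per-fly proportions.

    ``per_fly`` needs columns ``genotype``, ``age_days`` and ``value_col``
    (one row per fly).  Requires >= 2 genotypes and >= 2 age groups with at
    least 3 flies in every cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = per_fly.rename(columns={value_col: "value"}).copy()
    genos = sorted(df["genotype"].unique())
    ages = sorted(df["age_days"].unique())
    if len(genos) < 2:
        raise ParameterError("two-way design requires at least 2 genotypes")
    if len(ages) < 2:
        raise ParameterError("two-way design requires at least 2 age groups")
    for g in genos:
        for a in ages:
            n = len(df[(df["genotype"] == g) & (df["age_days"] == a)])
            if n < 3:
                raise DataError(
                    f"design cell genotype={g!r}, age={a} has {n} flies (< 3)"
                )
    model = smf.ols("value ~ C(genotype) * C(age_days)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    kruskal = {}
    for g in genos:
        groups = [df.loc[(df["genotype"] == g) & (df["age_days"] == a),
                         "value"].to_numpy() for a in ages]
        if all(np.all(grp == groups[0][0]) for grp in groups):
            kruskal[g] = 1.0
        else:
            kruskal[g] = float(stats.kruskal(*groups).pvalue)
    rows = []
    for g in genos:
        for a0, a1 in zip(ages[:-1], ages[1:]):
            x = df.loc[(df["genotype"] == g) & (df["age_days"] == a0),
                       "value"].to_numpy()
            y = df.loc[(df["genotype"] == g) & (df["age_days"] == a1),
                       "value"].to_numpy()
            pooled = np.concatenate([x, y])
            if np.all(pooled == pooled[0]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append({"genotype": g, "age_from": a0, "age_to": a1,
                         "pvalue": p, "significant_at_0.01": p < POSTHOC_ALPHA})
    return AgeTrendResult(response=response, anova=anova,
                          kruskal_by_genotype=kruskal,
                          posthoc=pd.DataFrame(rows))
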