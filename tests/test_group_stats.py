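from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import shadowtrial as st
from shadowtrial.errors import DataError, ParameterError
from shadowtrial.group_stats import (
    age_trend_analysis,
    compare_groups,
    dispersion_permutation_test,
    dispersion_statistic,
)
from shadowtrial.synthetic import (
    control_like,
    generate_cohort,
    parkin_like,
    shift_curve_stop_to_none,
)


def exact_mwu_p(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of group
    assignments (independent oracle for small tie-free samples)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in combinations(range(len(pooled)), n1)])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestCompareGroups:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(4, 8))
        y = rng.normal(0.8, 1, rng.integers(4, 8))
        res = compare_groups(x, y)
        assert res.pvalue == pytest.approx(exact_mwu_p(x, y), abs=1e-12)

    def test_identical_samples(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.percent_change == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_percent_change_arithmetic(self):
        res = compare_groups([10.0, 10.0, 10.0], [7.5, 7.5, 7.5])
        assert res.percent_change == pytest.approx(-25.0)
        assert res.direction == "decrease"

    def test_all_tied_degenerate(self):
        with pytest.warns(UserWarning):
            res = compare_groups([2.0] * 5, [2.0] * 5)
        assert res.pvalue == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        p1 = compare_groups(x, y).pvalue
        p2 = compare_groups(np.exp(x), np.exp(y)).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_planted_cohort_effect_recovered(self):
        """Parkin-like cohorts (walk speed x0.75, no-reaction x1.3) are
        distinguished from control-like ones at n=40 flies/group, with the
        speed decrease near the configured 25%."""
        sessions, _ = generate_cohort(
            {"control": control_like(n_flies=40),
             "parkin": parkin_like(n_flies=40)}, seed=7)
        trials = st.classify_cohort([(s, sch) for s, sch, _ in sessions])
        per_fly = trials[trials["valid"]].groupby(
            ["fly_id", "genotype"], as_index=False)["v_pre"].mean()
        ctrl = per_fly[per_fly["genotype"] == "control"]["v_pre"].to_numpy()
        mut = per_fly[per_fly["genotype"] == "parkin"]["v_pre"].to_numpy()
        res = compare_groups(ctrl, mut, labels=("control", "parkin"))
        assert res.pvalue < 0.05
        assert -35.0 < res.percent_change < -15.0
        prof = st.fly_profiles(trials)
        a = prof[prof["genotype"] == "control"]["p_no_reaction"].to_numpy()
        b = prof[prof["genotype"] == "parkin"]["p_no_reaction"].to_numpy()
        res2 = compare_groups(a, b)
        assert res2.pvalue < 0.05 and res2.percent_change > 0


class TestDispersion:
    def test_same_sample_twice(self):
        x = np.arange(10.0)
        p, obs = dispersion_permutation_test(x, x, n_perm=200, seed=0)
        assert obs == pytest.approx(0.0)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_statistic_location_invariant(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 3, 30)
        assert dispersion_statistic(a, b) == pytest.approx(
            dispersion_statistic(a + 100, b - 7), abs=1e-9)

    def test_seed_reproducibility_and_range(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 2, 20)
        p1, _ = dispersion_permutation_test(a, b, n_perm=500, seed=11)
        p2, _ = dispersion_permutation_test(a, b, n_perm=500, seed=11)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_zero_variance_both(self):
        p, obs = dispersion_permutation_test([1.0] * 5, [1.0] * 5,
                                             n_perm=100, seed=0)
        assert p == 1.0

    def test_large_variance_ratio_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, np.sqrt(10), 50)
        p, obs = dispersion_permutation_test(a, b, n_perm=999, seed=5)
        assert p < 0.01


class TestAgeTrend:
    def _per_fly(self, rng, effect=0.0, n=6):
        rows = []
        for g in ("a", "b"):
            for age in (7, 28):
                for i in range(n):
                    base = 0.4 - effect * (age == 28)
                    rows.append({"genotype": g, "age_days": age,
                                 "proportion": rng.normal(base, 0.05)})
        return pd.DataFrame(rows)

    def test_identical_cells_flat(self):
        # every cell holds the same six values: zero between-cell variance
        values = [0.30, 0.35, 0.40, 0.45, 0.50, 0.55]
        rows = [{"genotype": g, "age_days": a, "proportion": v}
                for g in ("a", "b") for a in (7, 28) for v in values]
        res = age_trend_analysis(pd.DataFrame(rows), "stop")
        assert res.anova.loc["C(age_days)", "F"] == pytest.approx(0.0, abs=1e-9)
        assert res.anova.loc["C(age_days)", "PR(>F)"] == pytest.approx(1.0)
        assert all(p > 0.99 for p in res.kruskal_by_genotype.values())

    def test_single_genotype_rejected(self):
        df = self._per_fly(np.random.default_rng(1))
        with pytest.raises(ParameterError):
            age_trend_analysis(df[df["genotype"] == "a"], "stop")

    def test_empty_cell_named(self):
        df = self._per_fly(np.random.default_rng(2))
        df = df[~((df["genotype"] == "b") & (df["age_days"] == 28))
                | (df.index % 6 == 0)]
        with pytest.raises(DataError, match="genotype='b'"):
            age_trend_analysis(df, "stop")

    def test_planted_decline_detected_synthetic(self):
        """Cohorts whose stop probability is halved at four weeks show a
        strong age main effect in the two-way ANOVA."""
        young = control_like(n_flies=5)
        old_curve = shift_curve_stop_to_none(young.response_curve, 0.5)
        groups = {
            "ctrl_young": young.replace(name="ctrl", age_days=7),
            "mut_young": parkin_like(n_flies=5, name="mut", age_days=7),
            "ctrl_old": young.replace(name="ctrl", age_days=28,
                                      response_curve=old_curve),
            "mut_old": parkin_like(n_flies=5, name="mut", age_days=28,
                                   response_curve=shift_curve_stop_to_none(
                                       parkin_like().response_curve, 0.5)),
        }
        sessions, _ = generate_cohort(groups, seed=31)
        trials = st.classify_cohort([(s, sch) for s, sch, _ in sessions])
        prof = st.fly_profiles(trials)
        per_fly = prof.rename(columns={"p_stop": "proportion"})[
            ["genotype", "age_days", "proportion"]]
        res = age_trend_analysis(per_fly, "stop")
        assert res.anova.loc["C(age_days)", "PR(>F)"] < 0.01
        assert not res.posthoc.empty
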