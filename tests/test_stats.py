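"""Tests for the statistical toolbox against independent oracles."""
import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metacog import (
    ContingencyTable,
    change_correlation,
    chi_square_independence,
    cross_sectional_regression,
    fisher_exact,
    group_time_anova,
    mixed_change_model,
    oneway_anova_from_summary,
    power_sample_size_correlation,
    time_by_covariate_interaction,
    tukey_hsd_from_summary,
    welch_t_from_summary,
    zscore,
)

# --- oracles ----------------------------------------------------------------


def chi2_loop_oracle(table):
    """Pearson chi-square by explicit cell loop."""
    table = np.asarray(table, float)
    n = table.sum()
    rows, cols = table.sum(1), table.sum(0)
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / n
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


def table_prob_exact(table, rows, cols, n) -> Fraction:
    """Exact multivariate hypergeometric probability as a Fraction."""
    num = Fraction(1)
    for r in rows:
        num *= math.factorial(int(r))
    for c in cols:
        num *= math.factorial(int(c))
    den = Fraction(math.factorial(int(n)))
    for x in np.asarray(table).flat:
        den *= math.factorial(int(x))
    return num / den


def all_tables_with_margins(rows, cols):
    """Naive enumeration by cartesian product over free cells."""
    rows, cols = list(rows), list(cols)
    nr, nc = len(rows), len(cols)
    free = [(i, j) for i in range(nr - 1) for j in range(nc - 1)]
    ranges = [range(min(rows[i], cols[j]) + 1) for i, j in free]
    for combo in itertools.product(*ranges):
        t = np.zeros((nr, nc), dtype=int)
        for (i, j), v in zip(free, combo):
            t[i, j] = v
        ok = True
        for i in range(nr - 1):
            t[i, -1] = rows[i] - t[i, :-1].sum()
            if t[i, -1] < 0:
                ok = False
                break
        if not ok:
            continue
        t[-1, :] = np.asarray(cols) - t[:-1, :].sum(0)
        if (t[-1, :] >= 0).all():
            yield t


def fisher_exact_fraction_oracle(table) -> float:
    """Freeman-Halton p via exact rational arithmetic."""
    table = np.asarray(table, int)
    rows, cols, n = table.sum(1), table.sum(0), table.sum()
    p_obs = table_prob_exact(table, rows, cols, n)
    total = Fraction(0)
    for t in all_tables_with_margins(rows, cols):
        p = table_prob_exact(t, rows, cols, n)
        if p <= p_obs:
            total += p
    return float(total)


def random_small_table(rng):
    while True:
        r, c = rng.integers(2, 4, size=2)
        t = rng.integers(0, 8, size=(r, c))
        if t.sum() <= 60 and (t.sum(0) > 0).all() and (t.sum(1) > 0).all():
            return t


# --- z-scoring and correlation ----------------------------------------------


def test_zscore_basic():
    np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])
    v = np.random.default_rng(0).normal(5, 3, 50)
    z = zscore(v)
    np.testing.assert_allclose(z, (v - v.mean()) / v.std(ddof=1))
    np.testing.assert_allclose(zscore(z), z, atol=1e-12)


def test_zscore_errors():
    with pytest.raises(ValueError):
        zscore([2.0])
    with pytest.raises(ValueError):
        zscore([3.0, 3.0, 3.0])


def test_change_correlation_perfect_negative():
    x = np.arange(10.0)
    r, df, p = change_correlation(x, -x)
    assert r == pytest.approx(-1.0)
    assert df == 8


def test_change_correlation_null_band(rng):
    x, y = rng.standard_normal((2, 1000))
    r, df, p = change_correlation(x, y)
    assert abs(r) < 0.1
    assert df == 998


def test_change_correlation_errors():
    with pytest.raises(ValueError):
        change_correlation([1, 1, 1], [1, 2, 3])


# --- summary tests ----------------------------------------------------------


def test_welch_identical_groups_zero():
    t, df, p = welch_t_from_summary(5, 1, 30, 5, 1, 30)
    assert t == 0.0
    assert p == pytest.approx(1.0)


def test_welch_matches_rawdata_oracle(rng):
    """Construct raw vectors with exact moments, compare with scipy."""
    for _ in range(5):
        m1, m2 = rng.normal(0, 2, 2)
        s1, s2 = rng.uniform(0.5, 3, 2)
        n1, n2 = rng.integers(5, 40, 2)

        def exact_vector(m, s, n):
            base = rng.standard_normal(n)
            base = (base - base.mean()) / base.std(ddof=1)
            return m + s * base

        x, y = exact_vector(m1, s1, n1), exact_vector(m2, s2, n2)
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=False)
        t, df, p = welch_t_from_summary(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


def test_welch_rejects_bad_inputs():
    with pytest.raises(ValueError):
        welch_t_from_summary(1, 0, 10, 2, 1, 10)
    with pytest.raises(ValueError):
        welch_t_from_summary(1, 1, 1, 2, 1, 10)


# --- contingency tests ------------------------------------------------------


def test_chi2_zero_for_expected_table():
    table = np.outer([10, 20], [5, 15]) / 50.0 * 50  # exactly its own expectation
    chi2, df, p = chi_square_independence(table.astype(int) * 10)
    # build a table exactly proportional to its margins
    t = np.outer([1, 2], [3, 4]) * 5
    chi2, df, p = chi_square_independence(t)
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)


def test_chi2_matches_loop_oracle(rng):
    for _ in range(25):
        t = random_small_table(rng)
        chi2, df, p = chi_square_independence(t)
        assert chi2 == pytest.approx(chi2_loop_oracle(t), abs=1e-10)
        assert df == (t.shape[0] - 1) * (t.shape[1] - 1)


def test_chi2_zero_margin_errors():
    with pytest.raises(ValueError):
        chi_square_independence([[0, 0], [3, 4]])


def test_fisher_single_column_is_one():
    assert fisher_exact(np.array([[3], [5], [2]])) == 1.0


def test_fisher_2x2_matches_scipy():
    for table in ([[1, 9], [11, 3]], [[4, 1], [2, 7]], [[10, 2], [3, 9]]):
        p = fisher_exact(np.array(table))
        assert p == pytest.approx(sps.fisher_exact(table)[1], abs=1e-10)


def test_fisher_enumeration_guard_suggests_monte_carlo():
    big = np.full((3, 3), 200)
    with pytest.raises(ValueError, match="monte-carlo"):
        fisher_exact(big)


def test_fisher_monte_carlo_close_to_enumeration():
    table = np.array([[8, 3, 4], [2, 9, 5]])
    exact = fisher_exact(table)
    mc = fisher_exact(table, method="monte-carlo", n_monte_carlo=40_000, seed=5)
    assert mc == pytest.approx(exact, abs=0.01)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, -1], [2, 3]]))
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[5]]))


# --- regression / mixed / anova --------------------------------------------


def test_cross_sectional_identity_predictor(rng):
    x = rng.standard_normal(80)
    data = pd.DataFrame({"y": x, "x": x})
    res = cross_sectional_regression(data, "y", ["x"])
    assert res["x"].estimate == pytest.approx(1.0)
    assert res["x"].p < 1e-20


def test_cross_sectional_rank_deficiency_detected(rng):
    x = rng.standard_normal(40)
    data = pd.DataFrame({"y": rng.standard_normal(40), "a": x, "b": 2 * x + 1})
    with pytest.raises(ValueError, match="rank deficient"):
        cross_sectional_regression(data, "y", ["a", "b"])


def test_cross_sectional_permutation_null(rng):
    ps = []
    for _ in range(40):
        data = pd.DataFrame(
            {"y": rng.standard_normal(60), "x": rng.standard_normal(60)}
        )
        ps.append(cross_sectional_regression(data, "y", ["x"])["x"].p)
    # p-values roughly uniform: KS test should not reject wildly
    stat = sps.kstest(ps, "uniform").pvalue
    assert stat > 0.01


def _paired_long(rng, n=16, effect=0.5):
    pre = rng.standard_normal(n)
    post = pre * 0.8 + effect + rng.standard_normal(n) * 0.4
    return pd.DataFrame(
        {
            "participant_id": list(range(n)) * 2,
            "time": [0] * n + [1] * n,
            "y": np.concatenate([pre, post]),
        }
    )


def test_mixed_model_equals_paired_difference(rng):
    """Two timepoints: the time fixed effect is the paired-difference mean."""
    data = _paired_long(rng)
    res = mixed_change_model(data, "y")
    z = zscore(data["y"])
    diffs = z[len(z) // 2 :] - z[: len(z) // 2]
    assert res["time"].estimate == pytest.approx(float(np.mean(diffs)), abs=1e-6)


def test_mixed_model_flat_outcome_zero_effect():
    n = 10
    data = pd.DataFrame(
        {
            "participant_id": list(range(n)) * 2,
            "time": [0] * n + [1] * n,
            "y": list(np.arange(n)) * 2,  # identical at both timepoints
        }
    )
    res = mixed_change_model(data, "y")
    assert res["time"].estimate == pytest.approx(0.0, abs=1e-10)


def test_mixed_model_recovers_injected_time_effect(rng):
    effects = []
    raw_effect = 0.6
    for _ in range(10):
        data = _paired_long(rng, n=120, effect=raw_effect)
        res = mixed_change_model(data, "y")
        # back-transform the standardised estimate to the raw scale
        effects.append(res["time"].estimate * data["y"].std(ddof=1))
    assert np.mean(effects) == pytest.approx(raw_effect, abs=0.12)


def test_mixed_model_drops_single_timepoint_participants(rng):
    data = _paired_long(rng, n=12)
    data = data.drop(index=[0])  # participant 0 loses baseline
    with pytest.warns(UserWarning, match="dropping 1"):
        res = mixed_change_model(data, "y")
    assert res.n == 11


def test_interaction_rejects_within_person_covariate(rng):
    data = _paired_long(rng, n=10)
    data["cov"] = rng.standard_normal(len(data))  # varies within person
    with pytest.raises(ValueError, match="varies within person"):
        time_by_covariate_interaction(data, "y", "cov")


def test_interaction_recovers_negative_coupling(rng):
    n = 300
    cov = rng.standard_normal(n)
    pre = rng.standard_normal(n)
    post = pre + 0.3 - 0.5 * cov + rng.standard_normal(n) * 0.3
    data = pd.DataFrame(
        {
            "participant_id": list(range(n)) * 2,
            "time": [0] * n + [1] * n,
            "y": np.concatenate([pre, post]),
            "cov": list(cov) * 2,
        }
    )
    res = time_by_covariate_interaction(data, "y", "cov")
    assert res["time:cov"].estimate < 0
    assert res["time:cov"].p < 1e-6


def test_interaction_null_covariate(rng):
    ps = []
    for _ in range(20):
        data = _paired_long(rng, n=60)
        per_person = dict(zip(range(60), rng.standard_normal(60)))
        data["cov"] = data["participant_id"].map(per_person)
        ps.append(time_by_covariate_interaction(data, "y", "cov")["time:cov"].p)
    assert min(ps) > 1e-4  # no spurious strong effect
    assert np.mean(np.array(ps) < 0.05) < 0.25


def test_interaction_categorical_covariate(rng):
    data = _paired_long(rng, n=90)
    groups = dict(zip(range(90), rng.choice(["a", "b", "c"], 90)))
    data["prog"] = data["participant_id"].map(groups)
    res = time_by_covariate_interaction(data, "y", "prog")
    inter_terms = [t.term for t in res.terms if t.term.startswith("time:prog")]
    assert len(inter_terms) == 2  # one per non-reference level


def _three_arm_long(rng, n_per_arm=(100, 40, 40), effect=0.0):
    rows = []
    pid = 0
    for arm, n in zip(("icbt", "anti", "ctrl"), n_per_arm):
        for _ in range(n):
            base = rng.standard_normal()
            shift = effect if arm != "ctrl" else 0.0
            rows.append((pid, arm, 0, base + rng.normal(0, 0.3)))
            rows.append((pid, arm, 1, base + shift + rng.normal(0, 0.3)))
            pid += 1
    return pd.DataFrame(rows, columns=["participant_id", "arm", "time", "y"])


def test_anova_flat_outcome_gives_zero_F(rng):
    data = _three_arm_long(rng, (5, 5, 5))
    data["y"] = 2.5
    res = group_time_anova(data, "y")
    assert all(t.stat == 0.0 and t.p == 1.0 for t in res.terms)


def test_anova_df_convention_matches_observation_level(rng):
    data = _three_arm_long(rng, (649, 82, 88))
    res = group_time_anova(data, "y")
    assert res["time"].df2 == 1632  # 1638 observations - 6 parameters
    assert res["group"].df1 == 2
    data["cov"] = data.groupby("participant_id")["y"].transform("mean")
    res3 = group_time_anova(data, "y", covariate="cov")
    assert res3["time:cov"].df2 == 1626  # 12 parameters in the 3-way model


def test_anova_detects_group_by_time_interaction(rng):
    data = _three_arm_long(rng, (150, 80, 80), effect=-0.8)
    res = group_time_anova(data, "y")
    assert res["group:time"].p < 0.01
    assert res["time"].p < 0.01


def test_anova_empty_group_errors(rng):
    data = _three_arm_long(rng, (10, 10, 10))
    with pytest.raises(ValueError):
        group_time_anova(data[data["arm"] == "icbt"], "y")


# --- one-way ANOVA / Tukey from summaries ------------------------------------


def test_oneway_equal_means_zero_F():
    F, df1, df2, p = oneway_anova_from_summary([(5, 1, 20), (5, 2, 30), (5, 1.5, 10)])
    assert F == 0.0
    assert p == pytest.approx(1.0)


def test_oneway_matches_rawdata_oracle(rng):
    groups = []
    raw = []
    for _ in range(3):
        n = int(rng.integers(8, 30))
        x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n)
        groups.append((x.mean(), x.std(ddof=1), n))
        raw.append(x)
    F, df1, df2, p = oneway_anova_from_summary(groups)
    F_ref, p_ref = sps.f_oneway(*raw)
    assert F == pytest.approx(F_ref, rel=1e-10)
    assert p == pytest.approx(p_ref, rel=1e-8)


def test_tukey_monotone_in_mean_difference():
    ps = []
    for diff in (0.2, 0.5, 1.0, 2.0):
        out = tukey_hsd_from_summary([(0, 1, 30), (diff, 1, 30), (5, 1, 30)])
        row = out[(out.group_1 == "g1") & (out.group_2 == "g2")]
        ps.append(float(row["p_adjusted"].iloc[0]))
    assert ps == sorted(ps, reverse=True)
    assert all(0 <= p <= 1 for p in ps)


def test_tukey_matches_scipy_rawdata(rng):
    raw = [rng.normal(m, 1, 25) for m in (0.0, 0.6, 1.0)]
    groups = [(x.mean(), x.std(ddof=1), len(x)) for x in raw]
    ours = tukey_hsd_from_summary(groups)
    ref = sps.tukey_hsd(*raw)
    for k, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
        assert ours["p_adjusted"].iloc[k] == pytest.approx(
            ref.pvalue[i, j], abs=1e-8
        )


# --- power ------------------------------------------------------------------


def test_power_monotone_and_limits():
    ns = [power_sample_size_correlation(r) for r in (0.1, 0.2, 0.3, 0.5, 0.9)]
    assert ns == sorted(ns, reverse=True)
    assert power_sample_size_correlation(0.99) <= 6
    with pytest.raises(ValueError):
        power_sample_size_correlation(0.0)
    with pytest.raises(ValueError):
        power_sample_size_correlation(0.5, power=1.2)


def test_power_matches_simulation_oracle(rng):
    """Monte-Carlo power curve agrees with the Fisher-z requirement +/- 2."""
    target_r, power, alpha = 0.5, 0.80, 0.05
    claimed = power_sample_size_correlation(target_r, power, alpha)

    def mc_power(n, reps=3000):
        x = rng.standard_normal((reps, n))
        y = target_r * x + math.sqrt(1 - target_r**2) * rng.standard_normal((reps, n))
        xm = x - x.mean(1, keepdims=True)
        ym = y - y.mean(1, keepdims=True)
        r = (xm * ym).sum(1) / np.sqrt((xm**2).sum(1) * (ym**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), n - 2)
        return float((p < alpha).mean())

    assert mc_power(claimed + 2) >= power - 0.03
    assert mc_power(max(4, claimed - 3)) <= power + 0.03
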