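import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antwalks.errors import InsufficientDataError, ParameterError
from antwalks.groupstats import (
    WALK_CONDITIONS,
    bootstrap_mean_diff,
    helmert_contrasts,
    helmert_table,
    repeated_contrast_test,
    tukey_pairwise,
    welch_anova,
    welch_t_test,
)


def brute_welch_t(a, b):
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def brute_welch_F(groups):
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    mean = np.array([np.mean(g) for g in groups])
    var = np.array([np.var(g, ddof=1) for g in groups])
    w = n / var
    mw = np.sum(w * mean) / np.sum(w)
    num = np.sum(w * (mean - mw) ** 2) / (k - 1)
    h = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    F = num / (1 + 2 * (k - 2) / (k**2 - 1) * h)
    df2 = (k**2 - 1) / (3 * h)
    return F, df2


def make_table(values):
    """values: dict ant -> (LW, E1, E2, E3) -> long-format metrics table."""
    rows = []
    for ant, vals in values.items():
        for cond, v in zip(WALK_CONDITIONS, vals):
            rows.append({"ant_id": ant, "condition": cond, "speed": v})
    return pd.DataFrame(rows)


class TestHelmertCoefficients:
    def test_rows_orthogonal_and_zero_sum(self):
        rows = list(helmert_contrasts().values())
        for r in rows:
            assert r.sum() == pytest.approx(0.0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert rows[i] @ rows[j] == pytest.approx(0.0)

    def test_first_contrast_is_lw_vs_mean_excavation(self):
        c1 = list(helmert_contrasts().values())[0]
        vals = np.array([10.0, 4.0, 5.0, 6.0])  # LW, E1, E2, E3
        assert c1 @ vals == pytest.approx(10.0 - np.mean([4, 5, 6]))

    def test_third_contrast_is_e2_minus_e3(self):
        c3 = list(helmert_contrasts().values())[2]
        vals = np.array([10.0, 4.0, 5.0, 6.0])
        assert c3 @ vals == pytest.approx(5.0 - 6.0)

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ParameterError):
            helmert_contrasts(["a", "b", "c"])


class TestRepeatedContrast:
    def test_identical_conditions_give_null(self):
        table = make_table({f"a{i}": (3.0, 3.0, 3.0, 3.0) for i in range(6)})
        c1 = list(helmert_contrasts().values())[0]
        res = repeated_contrast_test(table, "speed", c1)
        assert res.estimate == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_arithmetic_on_four_ants(self):
        table = make_table({
            "a": (10.0, 4.0, 5.0, 6.0),
            "b": (12.0, 5.0, 5.0, 4.0),
            "c": (9.0, 6.0, 4.0, 5.0),
            "d": (11.0, 3.0, 6.0, 6.0),
        })
        c1 = list(helmert_contrasts().values())[0]
        per_ant = [10 - 5, 12 - 14 / 3, 9 - 5, 11 - 5]
        res = repeated_contrast_test(table, "speed", c1)
        assert res.estimate == pytest.approx(np.mean(per_ant))
        t, p = stats.ttest_1samp(per_ant, 0.0)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.df == 3

    def test_incomplete_ant_dropped_with_warning(self):
        table = make_table({f"a{i}": (10.0 + i, 4.0, 5.0, 6.0) for i in range(5)})
        table = table.drop(table[(table.ant_id == "a0") & (table.condition == "E3")].index)
        c1 = list(helmert_contrasts().values())[0]
        with pytest.warns(UserWarning, match="dropping 1 ant"):
            res = repeated_contrast_test(table, "speed", c1)
        assert res.n == 4

    def test_too_few_complete_ants(self):
        table = make_table({"a": (1.0, 2.0, 3.0, 4.0), "b": (1.0, 2.0, 3.0, 4.0)})
        c1 = list(helmert_contrasts().values())[0]
        with pytest.raises(InsufficientDataError):
            repeated_contrast_test(table, "speed", c1)

    def test_null_pvalues_are_uniform(self):
        # complete-design null: within-ant contrast values are iid normal
        rng = np.random.default_rng(42)
        c1 = list(helmert_contrasts().values())[0]
        pvals = []
        for _ in range(2000):
            vals = rng.normal(5.0, 1.0, size=(10, 4))
            table = make_table({f"a{i}": tuple(v) for i, v in enumerate(vals)})
            pvals.append(repeated_contrast_test(table, "speed", c1).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestWelchAnova:
    def test_identical_means(self):
        g = [np.array([1.0, 2.0, 3.0])] * 4
        res = welch_anova(g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_equal_welch_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 3, 15)
        F = welch_anova([a, b]).statistic
        t = welch_t_test(a, b).statistic
        assert F == pytest.approx(t**2, abs=1e-10)

    def test_matches_brute_force_and_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        groups = [rng.normal(i, 1 + i, 12) for i in range(4)]
        res = welch_anova(groups)
        F, df2 = brute_welch_F(groups)
        assert res.statistic == pytest.approx(F, abs=1e-10)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(np.arange(4), 12),
        })
        pg = pingouin.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(pg.loc[0, "F"], abs=1e-8)
        assert res.p == pytest.approx(pg.loc[0, "p_unc"], abs=1e-8)

    def test_type_one_error_under_unequal_variances(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 5000
        for _ in range(reps):
            groups = [rng.normal(0, sd, 20) for sd in (1.0, 1.0, 3.0)]
            hits += welch_anova(groups).p < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestWelchT:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t_test(a, a.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 5)
        res = welch_t_test(a, b)
        t, df, p = brute_welch_t(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_equal_variance_limit_df(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 40)
        a, b = base, rng.permutation(base) + 0.1
        res = welch_t_test(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2, rel=0.01)


class TestTukey:
    def test_identical_groups_all_null(self):
        table = make_table({f"a{i}": (2.0, 2.0, 2.0, 2.0) for i in range(5)})
        for res in tukey_pairwise(table, "speed"):
            assert res.p == pytest.approx(1.0)

    def test_adjusted_at_least_paired_t(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(5, 1, size=(8, 4))
        table = make_table({f"a{i}": tuple(v) for i, v in enumerate(vals)})
        wide = {c: vals[:, j] for j, c in enumerate(WALK_CONDITIONS)}
        for res in tukey_pairwise(table, "speed"):
            c1, _, c2 = res.contrast_id.split(" ")
            raw_p = stats.ttest_rel(wide[c1], wide[c2]).pvalue
            assert res.p >= raw_p - 1e-10

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(7)
        hits = {pair: 0 for pair in ("LW vs E1", "LW vs E2", "LW vs E3")}
        others = 0
        reps = 60
        for _ in range(reps):
            vals = rng.normal(5, 1, size=(12, 4))
            vals[:, 0] += 4.0  # LW shifted by 4 within-ant sd
            table = make_table({f"a{i}": tuple(v) for i, v in enumerate(vals)})
            for res in tukey_pairwise(table, "speed"):
                if res.contrast_id in hits:
                    hits[res.contrast_id] += res.p < 0.01
                else:
                    others += res.p < 0.01
        for pair, n_sig in hits.items():
            assert n_sig >= 0.95 * reps, pair
        assert others <= 0.10 * reps * 3


class TestBootstrap:
    def test_identical_samples_straddle_zero(self):
        a = np.arange(10.0)
        out = bootstrap_mean_diff(a, a.copy(), seed=0)
        assert out["ci_lo"] < 0 < out["ci_hi"]

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        o1 = bootstrap_mean_diff(a, b, seed=3)
        o2 = bootstrap_mean_diff(a, b, seed=3)
        assert o1 == o2

    def test_interval_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        wins = 0
        reps = 100
        for i in range(reps):
            small_a, small_b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
            big_a, big_b = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
            w_small = np.subtract(*reversed(
                [bootstrap_mean_diff(small_a, small_b, seed=i)[k] for k in ("ci_lo", "ci_hi")]
            ))
            w_big = np.subtract(*reversed(
                [bootstrap_mean_diff(big_a, big_b, seed=i)[k] for k in ("ci_lo", "ci_hi")]
            ))
            wins += w_big < w_small
        assert wins >= 0.95 * reps

    def test_small_n_boot_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_mean_diff(np.arange(5.0), np.arange(5.0), n_boot=100)


class TestHelmertTable:
    def test_three_contrasts_per_metric(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(5, 1, size=(6, 4))
        table = make_table({f"a{i}": tuple(v) for i, v in enumerate(vals)})
        results = helmert_table(table, "speed")
        assert len(results) == 3
        assert results[0].contrast_id.startswith("LW vs")
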