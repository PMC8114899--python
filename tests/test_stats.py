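"""Statistics layer vs independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from qeeg.errors import InputError
from qeeg.stats import (bootstrap_mean_difference, compare_groups_t,
                        grubbs_test, render_estimation_data, sidak_posthoc,
                        significance_code, two_way_anova_power)


# ---------------------------------------------------------------------------
# test-local oracles
# ---------------------------------------------------------------------------

def oracle_t(a, b):
    """Closed-form pooled/Welch t with an F-ratio variance pre-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    hi, lo = max(va, vb), min(va, vb)
    dfh = (na if va >= vb else nb) - 1
    dfl = (nb if va >= vb else na) - 1
    p_var = min(1.0, 2 * sst.f.sf(hi / lo, dfh, dfl)) if lo > 0 else 0.0
    welch = p_var < 0.05
    diff = a.mean() - b.mean()
    if welch:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1)
                                         + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    t = diff / se
    return t, df, 2 * sst.t.sf(abs(t), df), welch


def oracle_anova_projection(table):
    """Type III two-way ANOVA via explicit sum-coded projection matrices."""
    genos = sorted(table["genotype"].unique())
    freqs = sorted(table["frequency"].unique())
    y = table["value"].to_numpy(float)
    n = len(y)

    def sum_code(values, levels):
        k = len(levels)
        X = np.zeros((len(values), k - 1))
        for j, lev in enumerate(levels[:-1]):
            X[:, j] = (values == lev).astype(float)
        X[np.asarray(values) == levels[-1], :] = -1.0
        return X

    A = sum_code(table["genotype"].to_numpy(), genos)
    B = sum_code(table["frequency"].to_numpy(), freqs)
    AB = np.column_stack([A[:, i] * B[:, j]
                          for i in range(A.shape[1]) for j in range(B.shape[1])])
    I = np.ones((n, 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full = np.hstack([I, A, B, AB])
    rss_full = rss(full)
    df_err = n - full.shape[1]
    out = {}
    for name, drop in (("genotype", A), ("frequency", B), ("interaction", AB)):
        cols = [I] + [M for M in (A, B, AB) if M is not drop]
        ss = rss(np.hstack(cols)) - rss_full
        df1 = drop.shape[1]
        F = (ss / df1) / (rss_full / df_err)
        out[name] = (F, df1, df_err, sst.f.sf(F, df1, df_err))
    return out


def random_table(rng, balanced=True, n_geno=2, n_freq=3):
    rows = []
    for gi in range(n_geno):
        for fi in range(n_freq):
            n = 5 if balanced else int(rng.integers(3, 8))
            mu = rng.normal(0, 5)
            for v in rng.normal(mu, 1.0, n):
                rows.append({"value": v, "genotype": f"g{gi}", "frequency": fi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t test
# ---------------------------------------------------------------------------

class TestCompareGroupsT:
    def test_identical_groups(self):
        res = compare_groups_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_pooled_example_closed_form(self):
        # oracle: t = (x̄_a − x̄_b) / (s_p·√(1/n_a + 1/n_b)) = −10.954, df 6
        res = compare_groups_t([1, 2, 3, 4], [11, 12, 13, 14])
        assert res.welch_used is False
        assert res.t == pytest.approx(-10.954451150103322, rel=1e-10)
        assert res.df == 6

    def test_variance_ratio_triggers_welch(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 10, 10)
        assert compare_groups_t(a, b).welch_used is True

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            a = rng.normal(0, rng.uniform(0.5, 5), int(rng.integers(3, 15)))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 5),
                           int(rng.integers(3, 15)))
            res = compare_groups_t(a, b)
            t, df, p, welch = oracle_t(a, b)
            assert res.welch_used == welch
            assert res.t == pytest.approx(t, rel=1e-10)
            assert res.df == pytest.approx(df, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-10)

    def test_ci_contains_difference(self):
        res = compare_groups_t([1, 2, 3, 4], [2, 3, 4, 5])
        diff = np.mean([1, 2, 3, 4]) - np.mean([2, 3, 4, 5])
        assert res.ci95[0] <= diff <= res.ci95[1]

    def test_too_small_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups_t([1], [1, 2])


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

class TestTwoWayAnova:
    def test_identical_values_no_effects(self):
        rows = [{"value": 7.0, "genotype": g, "frequency": f}
                for g in "ab" for f in range(3) for _ in range(4)]
        res = two_way_anova_power(pd.DataFrame(rows))
        assert res.F_genotype == 0.0 and res.p_genotype == 1.0
        assert res.F_frequency == 0.0 and res.p_frequency == 1.0
        assert res.F_interaction == 0.0 and res.p_interaction == 1.0

    @pytest.mark.parametrize("balanced", [True, False])
    def test_matches_projection_oracle(self, balanced):
        rng = np.random.default_rng(7 if balanced else 8)
        for _ in range(30 if balanced else 15):
            table = random_table(rng, balanced=balanced)
            res = two_way_anova_power(table)
            ora = oracle_anova_projection(table)
            for name, (F, df1, df2, p) in ora.items():
                got_F = getattr(res, f"F_{name}")
                got_df = getattr(res, f"df_{name}")
                got_p = getattr(res, f"p_{name}")
                assert got_F == pytest.approx(F, rel=1e-8), name
                assert got_df == (df1, df2), name
                assert got_p == pytest.approx(p, rel=1e-6, abs=1e-12), name

    def test_location_invariance(self):
        rng = np.random.default_rng(9)
        table = random_table(rng)
        shifted = table.assign(value=table["value"] + 1000.0)
        r1, r2 = two_way_anova_power(table), two_way_anova_power(shifted)
        assert r1.F_genotype == pytest.approx(r2.F_genotype, rel=1e-8)
        assert r1.F_interaction == pytest.approx(r2.F_interaction, rel=1e-8)

    def test_df_convention_51_levels(self):
        rng = np.random.default_rng(10)
        rows = [{"value": rng.normal(), "genotype": g, "frequency": f}
                for g in ("WT", "AS") for f in range(51) for _ in range(8)]
        res = two_way_anova_power(pd.DataFrame(rows))
        assert res.df_interaction[0] == 50
        assert res.df_genotype[0] == 1

    def test_empty_cell_named_in_error(self):
        table = pd.DataFrame([
            {"value": 1.0, "genotype": "a", "frequency": 0},
            {"value": 2.0, "genotype": "a", "frequency": 1},
            {"value": 3.0, "genotype": "b", "frequency": 0},
        ])
        with pytest.raises(InputError, match="genotype='b'"):
            two_way_anova_power(table)


# ---------------------------------------------------------------------------
# Sidak post hoc
# ---------------------------------------------------------------------------

class TestSidak:
    def test_single_comparison_unadjusted(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, n_freq=2)
        rows = sidak_posthoc(table)
        # m = 2 here; check formula directly for any m via monotone map
        anova = two_way_anova_power(table)
        for row in rows:
            assert row.p_adj >= 0.0

    def test_formula_value(self):
        # p_adj = 1 − (1 − p_raw)^m, the printed multiple-comparison rule
        assert 1 - (1 - 0.01) ** 51 == pytest.approx(0.4010, abs=1e-4)

    def test_adjustment_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(12)
        table = random_table(rng, n_freq=5)
        anova = two_way_anova_power(table)
        rows = sidak_posthoc(table, anova=anova)
        m = 5
        for row in rows:
            x1 = table.loc[(table.genotype == "g0")
                           & (table.frequency == row.frequency_hz), "value"]
            x2 = table.loc[(table.genotype == "g1")
                           & (table.frequency == row.frequency_hz), "value"]
            se = np.sqrt(anova.mse * (1 / len(x1) + 1 / len(x2)))
            t = (x1.mean() - x2.mean()) / se
            p_raw = 2 * sst.t.sf(abs(t), anova.df_resid)
            assert row.p_adj == pytest.approx(1 - (1 - p_raw) ** m, rel=1e-10)
            assert row.p_adj >= p_raw - 1e-15

    def test_equal_means_ci_straddles_zero(self):
        rows = []
        rng = np.random.default_rng(13)
        for g in ("a", "b"):
            for f in range(3):
                jitter = rng.normal(0, 1, 6)
                for v in (jitter - jitter.mean()):   # exactly equal cell means
                    rows.append({"value": v + f, "genotype": g, "frequency": f})
        out = sidak_posthoc(pd.DataFrame(rows))
        for row in out:
            assert row.ci95_diff[0] < 0 < row.ci95_diff[1]

    def test_significance_codes(self):
        assert significance_code(0.2) == "ns"
        assert significance_code(0.03) == "*"
        assert significance_code(0.004) == "**"
        assert significance_code(0.0004) == "***"
        assert significance_code(0.00004) == "****"


# ---------------------------------------------------------------------------
# Grubbs
# ---------------------------------------------------------------------------

class TestGrubbs:
    def test_obvious_outlier(self):
        res = grubbs_test([1, 1, 1, 1, 10])
        # oracle: G = |10 − 2.8| / s; crit from t(α/(2n), n−2)
        x = np.array([1, 1, 1, 1, 10], float)
        G = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        n = 5
        t = sst.t.ppf(1 - 0.05 / (2 * n), n - 2)
        crit = (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))
        assert res.G == pytest.approx(G, rel=1e-12)
        assert res.G_crit == pytest.approx(crit, rel=1e-12)
        assert res.is_outlier is True
        assert res.candidate_index == 4

    def test_symmetric_small_sample_no_outlier(self):
        assert grubbs_test([-1, 0, 1]).is_outlier is False

    def test_affine_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 12)
        r1 = grubbs_test(x)
        r2 = grubbs_test(5.0 * x + 100.0)
        assert r1.G == pytest.approx(r2.G, rel=1e-10)
        assert r1.candidate_index == r2.candidate_index

    def test_input_validation(self):
        with pytest.raises(InputError):
            grubbs_test([1, 2])
        with pytest.raises(InputError):
            grubbs_test([3, 3, 3, 3])


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_constant_groups_point_interval(self):
        with pytest.warns(RuntimeWarning):
            res = bootstrap_mean_difference([2, 2, 2], [2, 2, 2], n_boot=200)
        assert res.mean_diff == 0.0
        assert res.ci95_bca == (0.0, 0.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        r1 = bootstrap_mean_difference(a, b, n_boot=500, seed=7)
        r2 = bootstrap_mean_difference(a, b, n_boot=500, seed=7)
        assert r1.ci95_bca == r2.ci95_bca
        np.testing.assert_array_equal(r1.bootstrap_distribution,
                                      r2.bootstrap_distribution)

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1.2, 20)
        res = bootstrap_mean_difference(a, b, n_boot=2000, seed=1)
        assert res.ci95_bca[0] <= res.mean_diff <= res.ci95_bca[1]

    def test_reduces_to_percentile_when_symmetric(self):
        # symmetric-by-construction bootstrap: z0 ≈ 0, accel ≈ 0,
        # so the BCa interval must sit on the percentile interval
        rng = np.random.default_rng(17)
        base = rng.normal(0, 1, 10)
        a = np.concatenate([base, -base])          # exactly symmetric group
        b = np.concatenate([base + 1, -base + 1])
        res = bootstrap_mean_difference(a, b, n_boot=4000, seed=3)
        boot = res.bootstrap_distribution
        lo, hi = np.quantile(boot, [0.025, 0.975])
        width = hi - lo
        assert abs(res.bias_z0) < 0.08
        assert abs(res.accel) < 0.02
        assert res.ci95_bca[0] == pytest.approx(lo, abs=0.1 * width)
        assert res.ci95_bca[1] == pytest.approx(hi, abs=0.1 * width)

    def test_agrees_with_scipy_bca(self):
        # independent implementation of the same interval
        rng = np.random.default_rng(18)
        a, b = rng.normal(0, 1, 25), rng.exponential(1.0, 25)
        res = bootstrap_mean_difference(a, b, n_boot=9999, seed=5)
        ref = sst.bootstrap(
            (b, a), lambda y, x, axis=-1: np.mean(y, axis=axis) - np.mean(x, axis=axis),
            n_resamples=9999, confidence_level=0.95, method="BCa",
            random_state=np.random.default_rng(99), paired=False, vectorized=True)
        width = ref.confidence_interval.high - ref.confidence_interval.low
        assert res.ci95_bca[0] == pytest.approx(ref.confidence_interval.low,
                                                abs=0.08 * width)
        assert res.ci95_bca[1] == pytest.approx(ref.confidence_interval.high,
                                                abs=0.08 * width)

    def test_render_payload(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(0, 1, 10), rng.normal(2, 1, 10)
        res = bootstrap_mean_difference(a, b, n_boot=500, seed=2)
        data = render_estimation_data(res, a, b)
        assert data["group1"]["mean"] == pytest.approx(a.mean())
        assert data["group2"]["mean"] == pytest.approx(b.mean())
        assert data["ci95_bca"][0] <= data["bootstrap_quantiles"]["0.50"] \
            <= data["ci95_bca"][1]
        import json
        assert json.loads(json.dumps(data)) == data
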