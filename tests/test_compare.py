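"""Agreement statistics against brute-force and library oracles.

Every statistic is checked two ways: against sums-of-squares computed from
first principles in this file (explicit loops, no shared code with the
implementation) and, for the ICCs and the repeated-measures ANOVA, against
pingouin as an independent library oracle.
"""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from gaitpose.compare import (
    bin_by_walkway,
    difference_stats,
    icc_a1,
    icc_c1,
    mae_curves,
    match_events,
    pearson_r,
    rm_anova_bonferroni,
    xcorr_lag0,
)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent code paths)
# ---------------------------------------------------------------------------


def brute_force_mean_squares(data):
    n, k = data.shape
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(data[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def brute_force_iccs(x, y):
    data = np.column_stack([x, y])
    n, k = data.shape
    ms_r, ms_c, ms_e = brute_force_mean_squares(data)
    c1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    a1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    return c1, a1


def brute_force_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = (
        sum((x[i] - mx) ** 2 for i in range(n))
        * sum((y[i] - my) ** 2 for i in range(n))
    ) ** 0.5
    return num / den


def brute_force_rm_anova_F(data):
    n, k = data.shape
    grand = data.sum() / (n * k)
    ss_cond = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((data[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum(
        (data[i][j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


# ---------------------------------------------------------------------------
# Event matching
# ---------------------------------------------------------------------------


class TestMatchEvents:
    def test_identical_lists_fully_paired(self):
        a = np.array([0.3, 0.9, 1.5])
        m = match_events(a, a, 0.3)
        assert m.n == 3
        np.testing.assert_allclose(m.a - m.b, 0.0)

    def test_shifted_list_sign_convention(self):
        a = np.array([0.3, 0.9, 1.5])
        m = match_events(a, a + 0.01, 0.3)
        stats = difference_stats(m.a, m.b)
        assert stats["mean"] == pytest.approx(-0.01)

    def test_unpaired_events_reported(self):
        m = match_events([0.0, 1.0], [0.0, 5.0], 0.3)
        assert m.n == 1
        assert list(m.unmatched_a) == [1.0]
        assert list(m.unmatched_b) == [5.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_minimal_cost_assignment_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 5, rng.integers(3, 10)))
        b = np.sort(a + rng.normal(0, 0.05, len(a)))
        tol = 0.25
        m = match_events(a, b, tol)
        # oracle: exhaustive minimal-cost assignment with a large penalty for
        # out-of-tolerance pairs
        cost = np.abs(a[:, None] - b[None, :])
        penalty = 1e6
        cost = np.where(cost <= tol, cost, penalty)
        ri, ci = linear_sum_assignment(cost)
        oracle_pairs = [
            (a[i], b[j]) for i, j in zip(ri, ci) if cost[i, j] < penalty
        ]
        assert m.n == len(oracle_pairs)
        assert sum(abs(x - y) for x, y in zip(m.a, m.b)) == pytest.approx(
            sum(abs(x - y) for x, y in oracle_pairs), abs=1e-12
        )


class TestDifferenceStats:
    def test_identical_arrays_all_zero(self):
        s = difference_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s["mean"] == s["abs_mean"] == s["min"] == s["max"] == 0.0

    def test_constant_offset(self):
        s = difference_stats([1.0, 2.0], [0.5, 1.5])
        assert s["mean"] == pytest.approx(0.5)
        assert s["sd"] == pytest.approx(0.0)

    def test_random_pairs_match_direct_formulas(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=8)
        s = difference_stats(a, b)
        d = [a[i] - b[i] for i in range(8)]
        mean = sum(d) / 8
        sd = (sum((x - mean) ** 2 for x in d) / 7) ** 0.5
        assert s["mean"] == pytest.approx(mean, rel=1e-12)
        assert s["sd"] == pytest.approx(sd, rel=1e-12)
        assert s["abs_mean"] == pytest.approx(sum(abs(x) for x in d) / 8, rel=1e-12)
        assert s["min"] == pytest.approx(min(d))
        assert s["max"] == pytest.approx(max(d))


class TestCorrelations:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert icc_c1(x, x).value == pytest.approx(1.0)
        assert icc_a1(x, x).value == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged_missing(self):
        r, p = pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    @pytest.mark.parametrize("seed", range(8))
    def test_iccs_match_brute_force_anova(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.normal(1.0, 0.3, n)
        y = x + rng.normal(0.05, 0.1, n)
        c1_oracle, a1_oracle = brute_force_iccs(x, y)
        assert icc_c1(x, y).value == pytest.approx(c1_oracle, rel=1e-10)
        assert icc_a1(x, y).value == pytest.approx(a1_oracle, rel=1e-10)
        assert pearson_r(x, y)[0] == pytest.approx(
            brute_force_pearson(x, y), rel=1e-10
        )

    def test_iccs_match_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        x = rng.normal(0.6, 0.1, 12)
        y = x + rng.normal(0.02, 0.05, 12)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["a", "b"], 12),
                "scores": np.column_stack([x, y]).ravel(),
            }
        )
        icc = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        assert icc_c1(x, y).value == pytest.approx(icc.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert icc_a1(x, y).value == pytest.approx(icc.loc["ICC(A,1)", "ICC"], abs=1e-9)

    def test_agreement_icc_not_above_consistency_icc_when_bias_present(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0.6, 0.1, 10)
            y = x + rng.normal(0.1, 0.05, 10)  # systematic offset
            assert icc_a1(x, y).value <= icc_c1(x, y).value + 1e-12


class TestRMAnova:
    def test_identical_columns_give_F_zero_p_one(self):
        data = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        res = rm_anova_bonferroni(data)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_minimal_case_matches_hand_sums_of_squares(self):
        data = np.array([[1.0, 2.0, 3.0], [2.0, 2.5, 3.5]])
        res = rm_anova_bonferroni(data)
        assert res.F == pytest.approx(brute_force_rm_anova_F(data), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(int(rng.integers(3, 10)), 3))
        res = rm_anova_bonferroni(data)
        assert res.F == pytest.approx(brute_force_rm_anova_F(data), rel=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        data = rng.normal(size=(12, 3))
        res = rm_anova_bonferroni(data)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "system": np.tile(["MC", "CL", "CR"], 12),
                "value": data.ravel(),
            }
        )
        pg = pingouin.rm_anova(
            data=df, dv="value", within="system", subject="subject", correction=False
        )
        assert res.F == pytest.approx(float(pg["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(pg["p_unc"].iloc[0]), rel=1e-6)

    def test_offset_system_flagged_by_posthoc_at_large_n(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0.6, 0.05, 60)
        data = np.column_stack([base, base + rng.normal(0, 0.01, 60),
                                base + 0.05 + rng.normal(0, 0.01, 60)])
        res = rm_anova_bonferroni(data)
        assert res.p < 0.05
        assert res.posthoc_p[(0, 2)] < 0.05
        assert res.posthoc_p[(1, 2)] < 0.05
        assert res.posthoc_p[(0, 1)] > 0.05


class TestCycleComparisons:
    def test_identical_profiles(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 101))
        assert xcorr_lag0(x, x) == pytest.approx(1.0)
        assert mae_curves(x, x) == 0.0

    def test_negated_profile(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 101))
        assert xcorr_lag0(x, -x) == pytest.approx(-1.0)

    @pytest.mark.parametrize("phi", [0.0, 0.3, 1.0, np.pi / 2, 2.5])
    def test_phase_shifted_sine_gives_cos_phi(self, phi):
        # closed form: corr(sin(t), sin(t + phi)) over whole periods = cos(phi)
        n = 1000
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        assert xcorr_lag0(np.sin(t), np.sin(t + phi)) == pytest.approx(
            np.cos(phi), abs=1e-6
        )

    def test_constant_offset_mae(self):
        x = np.zeros(101)
        assert mae_curves(x, x + 3.0) == pytest.approx(3.0)


class TestWalkwayBins:
    def test_bin_bounds(self):
        positions = np.array([-0.7, 0.0, 0.6])
        values = np.array([1.0, 2.0, 3.0])
        out = bin_by_walkway(positions, values, center=0.0)
        assert out["Start"] == {"n": 1, "mae": 1.0}
        assert out["Middle"] == {"n": 1, "mae": 2.0}
        assert out["End"] == {"n": 1, "mae": 3.0}

    def test_center_defaults_to_midrange(self):
        positions = np.array([2.0, 3.0, 4.0])  # midrange 3.0
        values = np.array([1.0, 2.0, 3.0])
        out = bin_by_walkway(positions, values)
        assert out["Start"]["n"] == 1 and out["End"]["n"] == 1
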