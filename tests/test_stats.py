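import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from rodentsleep import stats


def brute_force_u_distribution(n_a, n_b):
    """Exhaustive U counts over all C(n_a+n_b, n_a) rank labelings."""
    counts = {}
    for comb in itertools.combinations(range(n_a + n_b), n_a):
        u = sum(comb) + n_a - n_a * (n_a + 1) // 2  # 0-based ranks -> U
        counts[u] = counts.get(u, 0) + 1
    return counts


class TestExactUTail:
    @pytest.mark.parametrize(
        "u, expected",
        [(3, 0.002), (6, 0.009), (8, 0.021), (2, 0.001)],
    )
    def test_published_p_values_n8_n7(self, u, expected):
        """Exact two-tailed p for the (n=8, n=7) strain comparison layout."""
        assert round(stats.exact_u_tail(u, 8, 7), 3) == expected

    def test_smallest_case_capped(self):
        assert stats.exact_u_tail(0, 1, 1) == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (4, 4), (5, 3), (6, 4)])
    def test_null_counts_match_enumeration(self, n_a, n_b):
        counts = stats._u_null_counts(n_a, n_b)
        brute = brute_force_u_distribution(n_a, n_b)
        for u in range(n_a * n_b + 1):
            assert counts[u] == brute.get(u, 0)
        assert sum(counts) == math.comb(n_a + n_b, n_a)

    def test_tied_u_rejected(self):
        with pytest.raises(ValueError, match="ties"):
            stats.exact_u_tail(3.5, 8, 7)


class TestMannWhitney:
    def test_full_ties_give_half_u_and_p1(self):
        res = stats.mannwhitney([1.0] * 8, [1.0] * 7)
        assert res.U == 28.0  # n_a*n_b/2
        assert res.p == 1.0

    def test_exact_p_matches_scipy(self, rng):
        for _ in range(20):
            a = rng.standard_normal(6)
            b = rng.standard_normal(5) + rng.uniform(-1, 1)
            res = stats.mannwhitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_permutation_handles_ties(self):
        a = [1, 2, 2, 3, 5]
        b = [2, 3, 3, 6, 7]
        res = stats.mannwhitney(a, b)
        assert res.method == "permutation"
        assert 0.0 < res.p <= 1.0

    def test_large_samples_use_normal_approx(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 1.0
        res = stats.mannwhitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "approx"
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)


class TestAUC:
    def test_identical_constants_half(self):
        assert stats.auc_effect([2.0, 2.0], [2.0, 2.0, 2.0]) == 0.5

    def test_complete_separation_one(self):
        assert stats.auc_effect([1, 2, 3], [4, 5]) == 1.0

    def test_antisymmetry_and_u_consistency(self, rng):
        for _ in range(200):
            a = rng.standard_normal(rng.integers(2, 10))
            b = rng.standard_normal(rng.integers(2, 10))
            auc = stats.auc_effect(a, b)
            assert auc == pytest.approx(1.0 - stats.auc_effect(b, a))
            res = stats.mannwhitney(a, b)
            frac = res.U / (len(a) * len(b))
            assert min(abs(auc - frac), abs(auc - (1 - frac))) < 1e-12

    def test_auc_from_u_orientations(self):
        assert stats.auc_from_u(3.0, 8, 7, b_larger=True) == pytest.approx(0.946, abs=5e-4)
        assert stats.auc_from_u(3.0, 8, 7, b_larger=False) == pytest.approx(0.054, abs=5e-4)


class TestBootstrapCI:
    def test_fully_separated_degenerate_interval(self):
        lo, hi = stats.bootstrap_auc_ci([1, 2, 3], [10, 11, 12], reps=500, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_identical_constants(self):
        lo, hi = stats.bootstrap_auc_ci([5, 5, 5], [5, 5], reps=500, seed=0)
        assert (lo, hi) == (0.5, 0.5)

    def test_deterministic_under_seed(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(7)
        assert stats.bootstrap_auc_ci(a, b, reps=300, seed=3) == stats.bootstrap_auc_ci(
            a, b, reps=300, seed=3
        )

    def test_interval_covers_point_auc(self):
        """Percentile interval contains the sample AUC in >= 90% of simulations."""
        rng = np.random.default_rng(11)
        cover = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.standard_normal(8)
            b = rng.standard_normal(7) + 0.5
            auc = stats.auc_effect(a, b)
            lo, hi = stats.bootstrap_auc_ci(a, b, reps=400, seed=int(rng.integers(2**31)))
            cover += lo - 1e-12 <= auc <= hi + 1e-12
        assert cover / n_sim >= 0.9


def oracle_mixed_anova(A, B):
    """Independent sums-of-squares computation via explicit cell loops."""
    import numpy as np

    k = A.shape[1]
    X = np.vstack([A, B])
    N = X.shape[0]
    grand = X.mean()
    ss_g = 0.0
    for G in (A, B):
        ss_g += G.shape[0] * k * (G.mean() - grand) ** 2
    ss_bs = sum(k * (row.mean() - grand) ** 2 for row in X)
    ss_swg = ss_bs - ss_g
    ss_t = sum(N * (X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_cells = 0.0
    for G in (A, B):
        for j in range(k):
            ss_cells += G.shape[0] * (G[:, j].mean() - grand) ** 2
    ss_int = ss_cells - ss_g - ss_t
    ss_err = ((X - grand) ** 2).sum() - ss_bs - ss_t - ss_int
    f_g = (ss_g / 1) / (ss_swg / (N - 2))
    f_t = (ss_t / (k - 1)) / (ss_err / ((N - 2) * (k - 1)))
    f_i = (ss_int / (k - 1)) / (ss_err / ((N - 2) * (k - 1)))
    return f_g, f_t, f_i


class TestMixedAnova:
    def test_identical_constant_groups(self):
        A = np.full((5, 4), 3.0)
        B = np.full((4, 4), 3.0)
        res = stats.rm_anova_sidak(A, B)
        assert res.f_strain == 0.0 and res.p_strain == 1.0

    def test_pure_group_shift_zero_noise(self):
        A = np.tile(np.arange(4.0), (5, 1))
        B = A[:4] + 2.0
        res = stats.rm_anova_sidak(A, B)
        assert res.f_strain == float("inf") and res.p_strain == 0.0
        assert res.f_interaction == 0.0

    def test_matches_ss_oracle(self, rng):
        for _ in range(20):
            A = rng.standard_normal((6, 12))
            B = rng.standard_normal((6, 12))
            res = stats.rm_anova_sidak(A, B)
            f_g, f_t, f_i = oracle_mixed_anova(A, B)
            assert res.f_strain == pytest.approx(f_g, abs=1e-8)
            assert res.f_time == pytest.approx(f_t, abs=1e-8)
            assert res.f_interaction == pytest.approx(f_i, abs=1e-8)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        A = rng.standard_normal((6, 5))
        B = rng.standard_normal((5, 5)) + 0.3
        res = stats.rm_anova_sidak(A, B)
        rows = []
        for gi, G in enumerate((A, B)):
            for si, row in enumerate(G):
                for ti, v in enumerate(row):
                    rows.append((f"g{gi}s{si}", gi, ti, v))
        df = pd.DataFrame(rows, columns=["subject", "group", "time", "y"])
        ref = pg.mixed_anova(df, dv="y", within="time", between="group",
                             subject="subject")
        ref = ref.set_index("Source")
        assert res.f_strain == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.f_time == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_posthoc_df_and_degrees(self, rng):
        A = rng.standard_normal((8, 12))
        B = rng.standard_normal((7, 12))
        res = stats.rm_anova_sidak(A, B)
        assert res.df_strain == (1, 13)
        assert res.df_time == (11, 143)
        assert len(res.posthoc) == 12
        assert (res.posthoc.p_sidak >= res.posthoc.p - 1e-12).all()


class TestSidak:
    def test_monotone_in_p_and_m(self):
        ps = np.linspace(0.001, 0.5, 20)
        adj = stats.sidak_adjust(ps, 12)
        assert (np.diff(adj) > 0).all()
        assert (stats.sidak_adjust(0.02, 15) > stats.sidak_adjust(0.02, 5))
        assert (adj >= ps).all()


class TestQQ:
    def test_standard_normal_slope_near_one(self):
        rng = np.random.default_rng(5)
        pts = stats.qq_points(rng.standard_normal(10_000))
        slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
        assert 0.95 <= slope <= 1.05

    def test_constant_sample_flat(self):
        pts = stats.qq_points([4.0] * 10)
        assert (pts[:, 1] == 4.0).all()

    def test_permutation_invariance(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(
            stats.qq_points(x), stats.qq_points(x[rng.permutation(50)])
        )

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.qq_points([1.0, 2.0])
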