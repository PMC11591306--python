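"""Statistics: rank tests vs enumeration/scipy oracles, regression,
chi-square, questionnaire scoring, log-age smoothing."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from circledraw.stats import (
    UndefinedTestError,
    chi_square_motivation,
    cronbach_alpha,
    group_statistics,
    mann_whitney_u_one_sided,
    motivation_score,
    paired_wilcoxon,
    regress_learning_on_age,
    smooth_vs_age,
    u_statistic,
    wilcoxon_signed_rank_one_sided,
)


def brute_w_plus(d):
    """Signed-rank statistic by definition (average ranks of |d|)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def exact_signed_rank_p(d, alternative="greater"):
    """Exact one-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    count = 0
    total = 2**n
    for signs in itertools.product([0, 1], repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if alternative == "greater" and w >= w_obs:
            count += 1
        elif alternative == "less" and w <= w_obs:
            count += 1
    return count / total


class TestSignedRank:
    def test_all_positive_gives_small_p(self):
        r = wilcoxon_signed_rank_one_sided([0.2, 0.5, 0.9, 0.4, 0.3, 0.7, 0.8])
        assert r.z_or_stat > 0
        assert r.p < 0.05

    def test_symmetric_values_near_half(self):
        vals = [0.3, -0.3, 0.7, -0.7, 1.1, -1.1, 0.5, -0.5]
        r = wilcoxon_signed_rank_one_sided(vals)
        assert 0.3 < r.p < 0.7

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank_one_sided([0.0, 0.0, 0.0, 0.0, 0.0])

    def test_statistic_matches_enumeration_oracle(self, rng):
        """W+ equals the brute-force definition for every n <= 8."""
        for n in range(3, 9):
            for _ in range(20):
                d = rng.normal(0.2, 1.0, n)
                d = d[d != 0]
                if len(d) == 0:
                    continue
                w = brute_w_plus(d)
                # recover W+ from our z: z = (W - mu - 0.5)/sd
                r = wilcoxon_signed_rank_one_sided(d)
                m = len(d)
                mu = m * (m + 1) / 4
                var = m * (m + 1) * (2 * m + 1) / 24
                _, counts = np.unique(np.abs(d), return_counts=True)
                var -= float((counts**3 - counts).sum()) / 48
                assert r.z_or_stat * math.sqrt(var) + mu + 0.5 == pytest.approx(w)

    def test_p_tracks_exact_enumeration(self, rng):
        # the normal approximation must agree with the exact one-sided p
        # to within a coarse tolerance at n = 8
        for _ in range(10):
            d = rng.normal(0.4, 1.0, 8)
            exact = exact_signed_rank_p(d)
            approx = wilcoxon_signed_rank_one_sided(d).p
            assert abs(exact - approx) < 0.08

    def test_monte_carlo_z_location(self, rng):
        """Seeded Normal(0.4, 0.5) draws: z near a resampling expectation."""
        zs = []
        for _ in range(30):
            vals = rng.normal(0.4, 0.5, 100)
            zs.append(wilcoxon_signed_rank_one_sided(vals).z_or_stat)
        # resampling oracle: same generator, scipy's statistic + moments
        zs_oracle = []
        for _ in range(30):
            vals = rng.normal(0.4, 0.5, 100)
            w, _ = sps.wilcoxon(vals, alternative="greater", method="approx")
            n = len(vals)
            mu, sd = n * (n + 1) / 4, math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
            zs_oracle.append((w - mu) / sd)
        se = np.std(zs_oracle, ddof=1) / math.sqrt(len(zs_oracle))
        assert abs(np.mean(zs) - np.mean(zs_oracle)) < 3 * se + 0.1


class TestPairedWilcoxon:
    def test_equal_pairs_undefined(self):
        with pytest.raises(UndefinedTestError):
            paired_wilcoxon([1.1, 1.2, 1.3, 1.4, 1.5], [1.1, 1.2, 1.3, 1.4, 1.5])

    def test_uniform_positive_shift_minimal_p(self):
        a = [1.15, 1.22, 1.31, 1.40, 1.18, 1.25]
        b = [x - 0.05 for x in a]
        r = paired_wilcoxon(a, b)
        # all differences positive: smallest achievable approx p for n=6
        assert r.p < 0.05
        assert r.z_or_stat > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2, 3], [1, 2])

    def test_type_one_error_under_iid_null(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            if paired_wilcoxon(a, b).p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se


class TestMannWhitney:
    def test_single_elements_exhaustive(self):
        assert u_statistic([1.0], [2.0]) == 0.0
        assert u_statistic([2.0], [1.0]) == 1.0

    def test_statistic_matches_enumeration_for_small_n(self, rng):
        """U equals the pair-count definition for all n1, n2 <= 8."""
        for n1 in range(1, 9):
            for n2 in range(1, 9):
                a = rng.normal(0, 1, n1)
                b = rng.normal(0.5, 1, n2)
                u_brute = u_statistic(a, b)
                u_scipy = sps.mannwhitneyu(a, b, alternative="greater").statistic
                assert u_brute == pytest.approx(float(u_scipy))
                # our z recovers the same U
                r = mann_whitney_u_one_sided(a, b)
                mu = n1 * n2 / 2
                n = n1 + n2
                var = n1 * n2 * (n + 1) / 12  # no ties in continuous draws
                assert r.z_or_stat * math.sqrt(var) + mu + 0.5 == pytest.approx(u_brute)

    def test_null_p_uniformity_by_permutation(self, rng):
        """Identical distributions: p approximately uniform across draws."""
        ps = []
        for _ in range(300):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0, 1, 12)
            ps.append(mann_whitney_u_one_sided(a, b).p)
        # mean of a uniform is 0.5 with SE 1/sqrt(12*300)
        assert abs(np.mean(ps) - 0.5) < 3 / math.sqrt(12 * 300) + 0.01
        rate = np.mean(np.array(ps) < 0.05)
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 300)

    def test_power_when_stochastically_larger(self, rng):
        ps = []
        for _ in range(50):
            a = rng.normal(0.8, 1, 30)
            b = rng.normal(0.0, 1, 30)
            ps.append(mann_whitney_u_one_sided(a, b).p)
        assert np.median(ps) < 0.05


class TestRegression:
    def test_perfect_line(self):
        ages = [7, 9, 11, 13, 15, 17, 18]
        vals = [0.1 * a for a in ages]
        r = regress_learning_on_age(ages, vals)
        assert r.slope == pytest.approx(0.1)
        assert r.r_squared == pytest.approx(1.0)

    def test_null_r_squared_near_zero(self, rng):
        ages = rng.integers(7, 60, 200)
        vals = rng.normal(0.5, 0.3, 200)
        r = regress_learning_on_age(ages, vals)
        assert r.r_squared < 0.05

    def test_adults_capped_identically(self):
        # adults at 40 and 60 contribute the same predictor: swapping their
        # values does not change the fit
        ages = [7, 10, 13, 16, 40, 60]
        vals = [0.1, 0.3, 0.2, 0.5, 0.4, 0.8]
        swapped = [0.1, 0.3, 0.2, 0.5, 0.8, 0.4]
        r1 = regress_learning_on_age(ages, vals)
        r2 = regress_learning_on_age(ages, swapped)
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.r_squared == pytest.approx(r2.r_squared)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            regress_learning_on_age([30, 40, 50], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_identical_distributions_zero(self):
        r = chi_square_motivation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.z_or_stat == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_disjoint_2x2_hand_value(self):
        # table (10,0 / 0,10): expected 5 each, chi2 = 4 * 25/5 = 20
        r = chi_square_motivation([1.0] * 10, [2.0] * 10)
        assert r.z_or_stat == pytest.approx(20.0)

    def test_df_is_levels_minus_one(self):
        # 9 observed half-point levels (two-item means) -> df = 8
        levels = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]
        a = levels * 2
        b = levels[::-1] * 2
        r = chi_square_motivation(a, b)
        expected_chi2, expected_p, dof, _ = sps.chi2_contingency(
            np.array([[2] * 9, [2] * 9]), correction=False
        )
        assert dof == 8  # structure check against scipy on the same shape
        assert 0 <= r.p <= 1


class TestQuestionnaire:
    def test_perfectly_correlated_items_alpha_one(self):
        base = np.array([1.0, 2, 3, 4, 5, 4, 3, 2])
        items = np.column_stack([base, base, base])
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self, rng):
        items = rng.integers(1, 6, size=(4000, 5)).astype(float)
        assert abs(cronbach_alpha(items)) < 0.1

    def test_best_pair_selected(self, rng):
        n = 3000
        latent = rng.normal(size=n)
        # items 0 and 2 share the latent factor strongly; others are noise
        items = np.column_stack([
            latent + 0.8 * rng.normal(size=n),
            rng.normal(size=n),
            latent + 0.8 * rng.normal(size=n),
            rng.normal(size=n),
        ])
        out = motivation_score(items)
        assert out.selected_pair == (0, 2)
        assert out.alpha_pair > out.alpha_all
        assert np.allclose(out.scores, items[:, [0, 2]].mean(axis=1))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedTestError):
            cronbach_alpha(np.array([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]]))


class TestSmoothing:
    def test_constant_values_give_constant_curve(self):
        curve = smooth_vs_age([7, 9, 12, 20, 40], [0.4] * 5)
        assert np.allclose(curve.value, 0.4)

    def test_tiny_bandwidth_recovers_data_point(self):
        ages = [8.0, 16.0]
        vals = [0.2, 0.9]
        curve = smooth_vs_age(ages, vals, bandwidth=1e-4, grid=[math.log(8.0)])
        assert curve.value[0] == pytest.approx(0.2, abs=1e-9)

    def test_symmetric_midpoint_is_mean(self):
        ages = [8.0, 18.0]
        mid = math.exp((math.log(8) + math.log(18)) / 2)
        curve = smooth_vs_age(ages, [0.0, 1.0], grid=[math.log(mid)])
        assert curve.value[0] == pytest.approx(0.5)

    def test_shift_equivariance_in_value(self):
        ages = [7, 9, 11, 14, 18, 30]
        vals = np.array([0.1, 0.4, 0.2, 0.6, 0.5, 0.7])
        c0 = smooth_vs_age(ages, vals)
        c1 = smooth_vs_age(ages, vals + 2.0)
        assert np.allclose(c1.value, c0.value + 2.0)

    def test_weights_monotone_in_distance(self):
        # a far point influences the estimate less than a near one
        curve_near = smooth_vs_age([8, 9], [0.0, 1.0], grid=[math.log(8)])
        curve_far = smooth_vs_age([8, 30], [0.0, 1.0], grid=[math.log(8)])
        assert curve_far.value[0] < curve_near.value[0]


class TestGroupStatistics:
    def test_full_results_structure_on_simulated_cohorts(self):
        import pandas as pd

        from circledraw.learner_sim import DEFAULT_ADULT, DEFAULT_CHILD, simulate_cohort
        from circledraw.metrics import summarize

        rows = []
        for group, params, seed in [
            ("child", DEFAULT_CHILD, 11), ("adult", DEFAULT_ADULT, 22)
        ]:
            for s in simulate_cohort(15, seed, params=params, render=False, group=group):
                out = summarize(s)
                d = out.__dict__.copy()
                rows.append(d)
        df = pd.DataFrame(rows)
        res = group_statistics(df)
        assert set(res["groups"]) == {"child", "adult"}
        for g in res["groups"].values():
            assert g["learning_test"]["p"] < 0.05  # both groups learn
            assert g["variability_test"]["z"] > 0  # failure > success
        assert "learning_child_vs_adult" in res
        assert res["variability_fail_child_vs_adult"]["p"] < 0.5
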