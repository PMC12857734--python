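"""Surrogate permutation test, star rule, KS comparison, normality gate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daquant import (
    PermutationSpec,
    gen_group_samples,
    GroupSampleSpec,
    ks_two_sample,
    normality_gate,
    shapiro_pvalues,
    significance_stars,
    surrogate_permutation_test,
)


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "count,stars",
        [(9, "***"), (10, "**"), (99, "**"), (100, "*"), (499, "*"), (500, "ns")],
    )
    def test_thresholds_at_10000(self, count, stars):
        assert significance_stars(count, 10_000) == stars

    @pytest.mark.parametrize("n", [1000, 2000, 10_000, 20_000])
    def test_thresholds_scale_proportionally(self, n):
        assert significance_stars(int(0.05 * n), n) == "ns"
        assert significance_stars(int(0.05 * n) - 1, n) == "*"
        assert significance_stars(int(0.001 * n) - 1, n) == "***"

    def test_count_out_of_range(self):
        with pytest.raises(ValueError):
            significance_stars(11, 10)


class TestSurrogatePermutation:
    def test_exhaustive_small_case(self):
        """All 6 splits of [0,0]|[10,10]: two reach the observed delta of 10."""
        res = surrogate_permutation_test(
            [0.0, 0.0], [10.0, 10.0], PermutationSpec(exhaustive=True)
        )
        assert res.method == "exhaustive"
        assert res.n_surrogates == 6
        assert res.exceedance_count == 2
        assert res.p_estimate == pytest.approx(1 / 3)

    def test_identical_multisets_never_significant(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        res = surrogate_permutation_test(x, x.copy(), PermutationSpec(seed=0))
        assert res.observed_delta == 0.0
        assert res.exceedance_count == res.n_surrogates
        assert res.stars == "ns"

    def test_determinism_and_p_grid(self, rng):
        a, b = rng.lognormal(3, 0.6, 12), rng.lognormal(3, 0.6, 15)
        spec = PermutationSpec(n_surrogates=4000, seed=77)
        r1 = surrogate_permutation_test(a, b, spec)
        r2 = surrogate_permutation_test(a, b, spec)
        assert r1 == r2
        assert r1.p_estimate == r1.exceedance_count / 4000

    def test_swap_symmetry_of_observed_delta(self, rng):
        a, b = rng.lognormal(3, 0.6, 10), rng.lognormal(3.4, 0.6, 14)
        r_ab = surrogate_permutation_test(a, b, PermutationSpec(2000, seed=5))
        r_ba = surrogate_permutation_test(b, a, PermutationSpec(2000, seed=5))
        assert r_ab.observed_delta == r_ba.observed_delta
        # same null distribution: p estimates agree within MC error
        se = math.sqrt(0.25 / 2000)
        assert abs(r_ab.p_estimate - r_ba.p_estimate) < 4 * se

    def test_monte_carlo_matches_exhaustive(self, rng):
        """MC p at N=10,000 converges to the enumerated p (3 MC SE)."""
        for n1, n2 in [(3, 3), (4, 4)]:
            for _ in range(10):
                a = rng.lognormal(3, 0.6, n1)
                b = rng.lognormal(3, 0.6, n2)
                ex = surrogate_permutation_test(a, b, PermutationSpec(exhaustive=True))
                mc = surrogate_permutation_test(
                    a, b, PermutationSpec(10_000, seed=int(rng.integers(2**31)))
                )
                se = math.sqrt(max(ex.p_estimate * (1 - ex.p_estimate), 1e-6) / 10_000)
                assert abs(mc.p_estimate - ex.p_estimate) <= 3 * se + 1e-12

    def test_zero_exceedance_warns_about_p_bound(self):
        a = np.arange(10) * 0.01
        b = 100.0 + np.arange(10)
        with pytest.warns(UserWarning, match="bounded"):
            res = surrogate_permutation_test(a, b, PermutationSpec(200, seed=1))
        assert res.p_estimate == 0.0

    def test_power_monotone_in_shift(self):
        """Rejection rate is non-decreasing in the injected mean shift."""
        rates = []
        for i, shift in enumerate([0.0, 15.0, 60.0]):
            rejections = 0
            n_rep = 40
            for r in range(n_rep):
                a, b = gen_group_samples(
                    GroupSampleSpec(20, 20, shift=shift, seed=1000 * i + r)
                )
                res = surrogate_permutation_test(
                    a, b, PermutationSpec(500, seed=7000 + 1000 * i + r)
                )
                rejections += res.stars != "ns"
            rates.append(rejections / n_rep)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    @pytest.mark.parametrize("bad", [([1.0], [1.0, 2.0]), ([np.nan, 1.0], [1.0, 2.0])])
    def test_invalid_groups_rejected(self, bad):
        with pytest.raises(ValueError):
            surrogate_permutation_test(*bad, PermutationSpec(10, seed=0))


class TestKsTwoSample:
    def test_identical_samples_d_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ks_two_sample(x, x).d_statistic == 0.0

    def test_disjoint_supports_d_one(self):
        res = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.d_statistic == 1.0

    def test_interleaved_d_half(self):
        assert ks_two_sample([1, 3], [2, 4]).d_statistic == pytest.approx(0.5)

    def test_small_samples_use_exact_method(self):
        assert ks_two_sample([1, 3], [2, 4]).method == "exact"
        assert ks_two_sample(np.arange(11), np.arange(11) + 0.5).method == "asymp"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestNormalityGate:
    @pytest.mark.parametrize(
        "pvals,branch",
        [
            ([0.2, 0.6], "parametric"),
            ([0.2, 0.01], "nonparametric"),
            ([0.05, 0.5], "nonparametric"),  # boundary: requires strictly > alpha
        ],
    )
    def test_branching(self, pvals, branch):
        assert normality_gate(pvals) == branch

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            normality_gate([])
        with pytest.raises(ValueError):
            normality_gate([1.2])

    def test_gate_from_samples(self, rng):
        normal = rng.normal(0, 1, 80)
        skewed = rng.lognormal(0, 1.2, 80)
        p_norm, p_skew = shapiro_pvalues(normal, skewed)
        assert normality_gate([p_norm]) == "parametric"
        assert normality_gate([p_norm, p_skew]) == "nonparametric"


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    data=st.lists(st.floats(-50, 50), min_size=4, max_size=10),
    split=st.integers(2, 8),
)
def test_p_estimate_always_on_grid_and_in_unit_interval(data, split):
    split = min(split, len(data) - 2)
    a, b = np.array(data[:split]), np.array(data[split:])
    res = surrogate_permutation_test(a, b, PermutationSpec(256, seed=3))
    assert 0.0 <= res.p_estimate <= 1.0
    assert res.p_estimate * 256 == pytest.approx(round(res.p_estimate * 256))
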