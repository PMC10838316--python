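"""Statistical routines vs brute-force enumeration oracles.

Each exact small-sample path is checked against a direct enumeration of
its null distribution, independent of the implementation under test.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from tdcsfem.exceptions import DegenerateDataError
from tdcsfem.stats import (
    ks_normality,
    mann_whitney_u,
    spearman_ci,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def brute_wilcoxon_p(a, b):
    """Two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(b, float) - np.asarray(a, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    lo = hi = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        lo += w <= w_obs + 1e-12
        hi += w >= w_obs - 1e-12
    total = 2**n
    return min(1.0, 2.0 * min(lo / total, hi / total))


def brute_mann_whitney_p(a, b):
    """Two-sided p by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_of(idx):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_of(range(na))
    n_tot = 0
    count = 0
    mean_u = len(a) * len(b) / 2.0
    for idx in itertools.combinations(range(len(pooled)), na):
        u = u_of(idx)
        n_tot += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / n_tot


def brute_spearman_p(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def rho(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return u @ v / math.sqrt((u @ u) * (v @ v))

    obs = abs(rho(rx, ry))
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        count += abs(rho(rx, np.array(perm))) >= obs - 1e-12
    return count / total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_constant_positive_shift_gives_minimal_statistic(self):
        a = np.arange(1.0, 9.0)
        rep = wilcoxon_signed_rank(a, a + 2.0)
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(2.0 / 2.0**8, rel=1e-12)

    def test_exact_p_matches_enumeration_n6(self):
        a = np.array([10.0, 12.0, 9.5, 14.0, 8.0, 11.0])
        b = np.array([11.5, 11.0, 12.0, 15.5, 9.0, 10.0])
        rep = wilcoxon_signed_rank(a, b)
        assert rep.p_value == pytest.approx(brute_wilcoxon_p(a, b),
                                            rel=1e-12)

    def test_exact_p_matches_enumeration_with_tied_ranks(self):
        a = np.zeros(7)
        b = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -2.0, 3.0])
        rep = wilcoxon_signed_rank(a, b)
        assert rep.p_value == pytest.approx(brute_wilcoxon_p(a, b),
                                            rel=1e-12)

    def test_agrees_with_scipy_exact_on_tie_free_data(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(0.4, 1.0, size=12)
        rep = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(b, a, method="exact")
        assert rep.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)

    def test_large_sample_normal_approximation_reasonable(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.5, 1.0, size=40)
        rep = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(b, a, method="approx", correction=False)
        assert rep.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(-20, 20), min_size=5, max_size=9))
    def test_exact_null_matches_enumeration_property(self, diffs):
        a = np.zeros(len(diffs))
        b = np.asarray(diffs, float)
        if (b == 0).any():
            b = b + 0.5
        try:
            rep = wilcoxon_signed_rank(a, b)
        except DegenerateDataError:
            return
        assert rep.p_value == pytest.approx(brute_wilcoxon_p(a, b),
                                            rel=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_two_by_two_matches_enumeration(self):
        a, b = [1.0, 2.0], [3.0, 4.0]
        rep = mann_whitney_u(a, b)
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(brute_mann_whitney_p(a, b),
                                            rel=1e-12)

    def test_exact_matches_enumeration_small_groups(self):
        a = [3.1, 0.2, 5.5, 2.2]
        b = [4.4, 6.1, 1.0]
        rep = mann_whitney_u(a, b)
        assert rep.p_value == pytest.approx(brute_mann_whitney_p(a, b),
                                            rel=1e-12)

    def test_identical_multisets_give_p_one(self):
        rep = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rep.p_value == pytest.approx(1.0, abs=0.05)

    def test_group_swap_leaves_p_unchanged(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(0.8, 1.0, size=12)
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            mann_whitney_u([], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_increasing_gives_rho_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rep = spearman_ci(x, np.exp(x))
        assert rep.statistic == pytest.approx(1.0)

    def test_monotone_decreasing_gives_rho_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rep = spearman_ci(x, [-v**3 for v in x])
        assert rep.statistic == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle_n4(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0]
        rep = spearman_ci(x, y)
        assert rep.p_value == pytest.approx(brute_spearman_p(x, y),
                                            rel=1e-12)

    def test_exact_p_matches_permutation_oracle_n7(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rep = spearman_ci(x, y)
        assert rep.p_value == pytest.approx(brute_spearman_p(x, y),
                                            rel=1e-12)

    def test_rho_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(0, 2.0, size=30)
        rep = spearman_ci(x, y)
        assert rep.statistic == pytest.approx(
            sps.spearmanr(x, y).statistic, rel=1e-12)

    def test_fisher_ci_brackets_rho_and_shrinks_with_n(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(0, 1.0, size=20)
        rep = spearman_ci(x, y)
        assert rep.ci_low <= rep.effect <= rep.ci_high
        x2 = rng.normal(size=200)
        y2 = x2 + rng.normal(0, 1.0, size=200)
        rep2 = spearman_ci(x2, y2)
        assert (rep2.ci_high - rep2.ci_low) < (rep.ci_high - rep.ci_low)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# ---------------------------------------------------------------------------
# KS normality
# ---------------------------------------------------------------------------

class TestKsNormality:
    def test_statistic_matches_hand_computed_five_point_example(self):
        # x = (-2, -1, 0, 1, 2): mean 0, sd sqrt(10/4); D is the largest
        # gap between the empirical staircase and Phi(x / sd)
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        sd = math.sqrt(10.0 / 4.0)
        cdf = [0.5 * (1 + math.erf(v / (sd * math.sqrt(2)))) for v in x]
        gaps = []
        for i, c in enumerate(cdf):
            gaps.append(abs((i + 1) / 5 - c))
            gaps.append(abs(i / 5 - c))
        rep = ks_normality(x)
        assert rep.statistic == pytest.approx(max(gaps), rel=1e-12)
        assert 0.0 <= rep.statistic <= 1.0

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            ks_normality([2.0, 2.0, 2.0, 2.0])

    def test_note_flags_estimated_parameters(self, rng):
        rep = ks_normality(rng.normal(size=25))
        assert "Lilliefors" in rep.note
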