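"""Shared statistical primitives: BH step-up, Spearman, Wilcoxon tests,
and empirical-Bayes variance moderation."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from straindrift.stats import (
    bh_adjust,
    moderate_variances,
    spearman_rho,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


def bh_oracle(p, m):
    """Literal step-up definition: min over j>=i of m*p_(j)/j, clipped."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    n = len(p)
    adj_sorted = np.empty(n)
    for i in range(n):
        adj_sorted[i] = min(
            min(m * sorted_p[j] / (j + 1) for j in range(i, n)), 1.0
        )
    out = np.empty(n)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, m, expected",
        [
            ([0.01, 0.02, 0.03], 3, [0.03, 0.03, 0.03]),
            ([0.5], 1, [0.5]),
        ],
    )
    def test_known_values(self, p, m, expected):
        assert np.allclose(bh_adjust(p, m).p_adj, expected)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            p = rng.uniform(size=n)
            m = n + int(rng.integers(0, 5))
            assert np.allclose(bh_adjust(p, m).p_adj, bh_oracle(p, m), atol=0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_property_monotone_and_dominates_raw(self, p):
        res = bh_adjust(p)
        assert np.all(res.p_adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(res.p_adj[order]) >= -1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        for _ in range(20):
            x = rng.integers(0, 5, size=15).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx, ry = rankdata(x), rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, y**3 + 5 * y) == pytest.approx(base, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


def signed_rank_enumeration(d, sidedness):
    """Exhaustive 2^n enumeration of sign assignments (independent oracle)."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    )
    sf = np.mean(ws >= w_obs - 1e-9)
    cdf = np.mean(ws <= w_obs + 1e-9)
    if sidedness == "greater":
        return sf
    if sidedness == "less":
        return cdf
    return min(1.0, 2 * min(sf, cdf))


def rank_sum_enumeration(x, y, sidedness):
    """Exhaustive C(n+m, n) enumeration of rank assignments."""
    from scipy.stats import rankdata

    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    all_ranks = np.arange(1, n + m + 1)
    us = np.array(
        [sum(c) - n * (n + 1) / 2 for c in itertools.combinations(all_ranks, n)]
    )
    sf = np.mean(us >= u_obs - 1e-9)
    cdf = np.mean(us <= u_obs + 1e-9)
    if sidedness == "greater":
        return sf
    if sidedness == "less":
        return cdf
    return min(1.0, 2 * min(sf, cdf))


class TestWilcoxonSignedRank:
    def test_all_positive_one_sided(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], sidedness="greater")
        assert res.p == pytest.approx(1 / 32)
        assert res.method == "exact"

    def test_degenerate_all_zero(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank(np.zeros(6))
        assert res.degenerate and res.p == 1.0

    @pytest.mark.parametrize("sidedness", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration(self, sidedness, rng):
        for _ in range(10):
            n = int(rng.integers(4, 11))
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d, sidedness=sidedness)
            assert res.p == pytest.approx(signed_rank_enumeration(d, sidedness), abs=1e-12)

    def test_exact_handles_tied_ranks(self, rng):
        # integer data create tied absolute differences; DP uses doubled ranks
        for _ in range(10):
            d = rng.integers(-4, 5, size=8).astype(float)
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(signed_rank_enumeration(d, "two-sided"), abs=1e-12)


class TestWilcoxonRankSum:
    def test_complete_separation_one_sided(self):
        x = np.arange(4.0)
        y = np.arange(4.0) + 10
        res = wilcoxon_rank_sum(x, y, sidedness="less")
        assert res.p == pytest.approx(1 / comb(8, 4))
        assert res.method == "exact"

    def test_identical_multisets_two_sided(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = wilcoxon_rank_sum(x, x.copy(), sidedness="two-sided")
        assert res.p >= 0.99

    @pytest.mark.parametrize("sidedness", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration(self, sidedness, rng):
        for _ in range(8):
            n = int(rng.integers(3, 7))
            m = int(rng.integers(3, 8))
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            res = wilcoxon_rank_sum(x, y, sidedness=sidedness)
            assert res.p == pytest.approx(rank_sum_enumeration(x, y, sidedness), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestModerateVariances:
    def test_identical_variances_unchanged(self):
        s2 = np.full(50, 2.5)
        mv = moderate_variances(s2, d=4)
        assert np.allclose(mv.s2_post, s2)

    def test_convex_combination_property(self, rng):
        s2 = rng.chisquare(4, size=200) / 4
        mv = moderate_variances(s2, d=4)
        lo = np.minimum(s2, mv.s0_2)
        hi = np.maximum(s2, mv.s0_2)
        assert np.all(mv.s2_post >= lo - 1e-12) and np.all(mv.s2_post <= hi + 1e-12)
        if np.isfinite(mv.d0):
            w = mv.d / (mv.d0 + mv.d)
            assert np.allclose(mv.s2_post, w * s2 + (1 - w) * mv.s0_2)

    def test_few_units_fall_back_to_no_shrinkage(self, rng):
        s2 = rng.chisquare(4, size=5)
        with pytest.warns(UserWarning):
            mv = moderate_variances(s2, d=4)
        assert mv.d0 == 0.0
        assert np.allclose(mv.s2_post, s2)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        d0_true, s0_true, d = 4.0, 2.0, 4
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        mv = moderate_variances(s2, d=d)
        assert mv.d0 == pytest.approx(d0_true, rel=0.25)
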