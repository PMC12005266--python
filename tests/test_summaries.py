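"""Mating-outcome statistics, with an independent linear-programming
oracle for the dip statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

from assortmate import summaries as sm
from assortmate._dip import dip_statistic, dip_test
from assortmate.fixtures import make_mate_pairs, make_two_cluster_pairs


# ---------------------------------------------------------------------------
# LP oracle: dip = min over unimodal CDFs U of sup |F_n - U|
# ---------------------------------------------------------------------------


def _dip_lp_interval_mode(x, k):
    """Minimal sup deviation with the mode strictly between x_{k-1} and x_k
    (k=0: all-concave; k=n: all-convex).  Variables u_0..u_{n-1}, eps.

    A mode point (x_m, .) inside the straddling interval must satisfy
    slope(x_{k-1}, x_m) >= s_L (last convex chord slope) on the left and
    slope(x_m, x_k) >= s_R (first concave chord slope) on the right; such
    an x_m exists iff u_k - u_{k-1} >= min(s_L, s_R) * (x_k - x_{k-1}).
    The min is handled as a disjunction of two LPs.
    """
    n = len(x)

    def solve(extra_branch):
        A, b = [], []

        def row(coeffs, rhs):
            r = np.zeros(n + 1)
            for i, c in coeffs:
                r[i] = c
            r[n] = -1.0  # -eps
            A.append(r)
            b.append(rhs)

        for i in range(n):
            row([(i, -1.0)], -(i + 1) / n)  # (i+1)/n - u_i <= eps
            row([(i, 1.0)], i / n)  # u_i - i/n <= eps
        for i in range(n - 1):  # monotone
            r = np.zeros(n + 1)
            r[i], r[i + 1] = 1.0, -1.0
            A.append(r)
            b.append(0.0)
        # slopes nondecreasing on the convex part (indices < k),
        # nonincreasing on the concave part (indices >= k)
        for i in range(n - 2):
            d1 = x[i + 1] - x[i]
            d2 = x[i + 2] - x[i + 1]
            r = np.zeros(n + 1)
            r[i] = -1.0 / d1
            r[i + 1] = 1.0 / d1 + 1.0 / d2
            r[i + 2] = -1.0 / d2
            if i + 2 <= k - 1:  # whole triple in convex part
                A.append(r)  # slope_i <= slope_{i+1}
                b.append(0.0)
            elif i >= k:  # whole triple in concave part
                A.append(-r)
                b.append(0.0)
        # cross-mode constraint on the straddling interval
        if 1 <= k <= n - 1:
            dx = x[k] - x[k - 1]
            if extra_branch == "left" and k >= 2:
                dl = x[k - 1] - x[k - 2]
                # (u_k - u_{k-1})/dx >= (u_{k-1} - u_{k-2})/dl
                r = np.zeros(n + 1)
                r[k] = -1.0 / dx
                r[k - 1] = 1.0 / dx + 1.0 / dl
                r[k - 2] = -1.0 / dl
                A.append(r)
                b.append(0.0)
            elif extra_branch == "right" and k <= n - 2:
                dr = x[k + 1] - x[k]
                # (u_k - u_{k-1})/dx >= (u_{k+1} - u_k)/dr
                r = np.zeros(n + 1)
                r[k] = -1.0 / dx - 1.0 / dr
                r[k - 1] = 1.0 / dx
                r[k + 1] = 1.0 / dr
                A.append(r)
                b.append(0.0)
            elif extra_branch == "left" and k == 1:
                pass  # convex part is a single point: s_L can be ~0
            elif extra_branch == "right" and k == n - 1:
                pass  # concave part is a single point: s_R can be ~0
        c = np.zeros(n + 1)
        c[n] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0.0, 1.0)] * (n + 1), method="highs")
        return res.fun if res.success else np.inf

    return min(solve("left"), solve("right"))


def _dip_lp_point_mode(x, k):
    """Mode at x_k with a jump allowed: extra variable v = U(x_k^-)."""
    n = len(x)
    nv = n + 1  # u_0..u_{n-1}, v; then eps
    A, b = [], []

    def add(coeffs, rhs):
        r = np.zeros(nv + 1)
        for i, c in coeffs:
            r[i] = c
        r[nv] = -1.0
        A.append(r)
        b.append(rhs)

    for i in range(n):
        add([(i, -1.0)], -(i + 1) / n)
        left = n if i == k else i  # U(x_i^-) is v at the mode
        add([(left, 1.0)], i / n)
    # monotone: u_0 <= ... <= u_{k-1} <= v <= u_k <= ... <= u_{n-1}
    order = list(range(k)) + [n] + list(range(k, n))
    for a_i, b_i in zip(order, order[1:]):
        r = np.zeros(nv + 1)
        r[a_i], r[b_i] = 1.0, -1.0
        A.append(r)
        b.append(0.0)
    # convex part: points 0..k-1 plus (x_k, v); concave: (x_k, u_k) plus k+1..
    left_pts = [(x[i], i) for i in range(k)] + [(x[k], n)]
    right_pts = [(x[k], k)] + [(x[i], i) for i in range(k + 1, n)]
    for pts, sign in ((left_pts, 1.0), (right_pts, -1.0)):
        for (xa, ia), (xb, ib), (xc, ic) in zip(pts, pts[1:], pts[2:]):
            d1, d2 = xb - xa, xc - xb
            r = np.zeros(nv + 1)
            r[ia] = -sign / d1
            r[ib] = sign / d1 + sign / d2
            r[ic] = -sign / d2
            A.append(r)
            b.append(0.0)
    c = np.zeros(nv + 1)
    c[nv] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                  bounds=[(0.0, 1.0)] * (nv + 1), method="highs")
    return res.fun if res.success else np.inf


def dip_lp_oracle(x):
    """Exhaustive mode search; feasible for small distinct samples."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    best = min(_dip_lp_interval_mode(x, k) for k in range(n + 1))
    for k in range(n):
        best = min(best, _dip_lp_point_mode(x, k))
    return best


def test_dip_known_values():
    assert dip_statistic(np.array([0.0, 1.0])) == pytest.approx(0.25)
    assert dip_statistic(np.array([0.0, 0.0, 1.0, 1.0])) == pytest.approx(0.25)
    assert dip_statistic(np.array([3.0, 3.0, 3.0])) == 0.0  # degenerate
    assert dip_statistic(np.array([5.0])) == 0.0
    # three equally spaced points: classical value 1/6
    assert dip_statistic(np.array([0.0, 0.5, 1.0])) == pytest.approx(1 / 6)
    assert dip_lp_oracle([0.0, 0.5, 1.0]) == pytest.approx(1 / 6, abs=1e-6)
    # equally spaced points attain the 1/(2n) lower bound
    assert dip_statistic(np.array([0, 1 / 3, 2 / 3, 1.0])) == \
        pytest.approx(1 / 8)


def test_dip_invariances(rng):
    x = rng.random(200)
    d = dip_statistic(x)
    assert dip_statistic(3.0 * x - 7.0) == pytest.approx(d)  # affine invariant
    assert dip_statistic(x**3) == pytest.approx(dip_statistic(np.sort(x) ** 3))


# grid-valued samples keep the oracle's slope coefficients (1/spacing)
# well conditioned; nearly-tied spacings overflow the LP numerically
@given(
    st.lists(
        st.integers(0, 64).map(lambda v: v / 64.0),
        min_size=4,
        max_size=11,
        unique=True,
    )
)
@settings(max_examples=60, deadline=None)
def test_dip_matches_lp_oracle(xs):
    got = dip_statistic(np.array(xs))
    want = dip_lp_oracle(xs)
    assert got == pytest.approx(want, abs=1e-6)


def test_dip_test_separates_modalities(rng):
    bimodal = np.concatenate(
        [rng.normal(0, 0.05, 300), rng.normal(1, 0.05, 300)]
    )
    d, p = dip_test(bimodal, n_boot=200, rng=rng)
    assert p < 0.01
    unimodal = rng.normal(0, 1, 600)
    d2, p2 = dip_test(unimodal, n_boot=200, rng=rng)
    assert p2 > 0.05
    assert d > d2


# ---------------------------------------------------------------------------
# Correlation and permutation test
# ---------------------------------------------------------------------------


def test_mate_correlation_basic():
    x = np.linspace(0, 1, 50)
    assert sm.mate_correlation((x, x)) == pytest.approx(1.0)
    assert sm.mate_correlation((x, 1 - x)) == pytest.approx(-1.0)
    assert np.isnan(sm.mate_correlation((np.ones(50), x)))  # constant column
    assert np.isnan(sm.mate_correlation((x[:1], x[:1])))


def test_mate_correlation_symmetrized(rng):
    rec = make_mate_pairs(2000, 0.5, seed=4)
    r = sm.mate_correlation(rec)
    rs = sm.mate_correlation(rec, symmetrize=True)
    assert abs(r - rs) < 0.05


def test_permutation_floor_for_strong_correlation(rng):
    x = np.linspace(0, 1, 200)
    res = sm.permutation_test((x, x), n_permutations=999, rng=rng)
    assert res.empirical_p == pytest.approx(1 / 1000)
    assert res.r_observed == pytest.approx(1.0)


def test_permutation_nan_sentinel(rng):
    res = sm.permutation_test((np.ones(20), np.ones(20)), rng=rng)
    assert np.isnan(res.empirical_p)


def test_permutation_p_uniform_under_null(rng):
    """Criterion-8 oracle: under independent columns the permutation p-value
    is (discretely) uniform."""
    ps = []
    for i in range(200):
        x1 = rng.random(60)
        x2 = rng.random(60)
        ps.append(sm.permutation_test((x1, x2), n_permutations=99,
                                      rng=rng).empirical_p)
    ps = np.array(ps)
    assert 0 < ps.min() and ps.max() <= 1
    assert abs(ps.mean() - 0.5) < 0.07  # 3 sigma ~ 0.06 for n=200
    frac_small = np.mean(ps <= 0.2)
    assert abs(frac_small - 0.2) < 0.1


# ---------------------------------------------------------------------------
# Delta-x, hexbin, bimodality, migrants, reproductive success
# ---------------------------------------------------------------------------


def test_delta_x_summary():
    x1 = np.array([0.0, 1.0, 0.5, 0.5])
    x2 = np.array([1.0, 1.0, 0.5, 0.0])
    d = sm.delta_x_distribution((x1, x2))
    assert d.mean == pytest.approx((1 + 0 + 0 + 0.5) / 4)
    assert d.hist_counts.sum() == 4
    assert d.quantiles[0.5] == pytest.approx(np.median([1, 0, 0, 0.5]))


def test_hexbin_count_conservation():
    rec = make_two_cluster_pairs(5000, seed=8)
    h = sm.hexbin_counts(rec)
    assert h.counts.sum() == 5000
    assert h.scaled.max() == pytest.approx(1.0)


def test_hexbin_single_point_one_cluster():
    x = np.full(500, 0.5)
    h = sm.hexbin_counts((x, x))
    assert h.n_clusters == 1


def test_hexbin_two_clusters():
    rec = make_two_cluster_pairs(5000, seed=2)
    assert sm.hexbin_counts(rec).n_clusters == 2


def test_bimodality_classifications(rng):
    uni = rng.normal(0.5, 0.05, 800)
    res = sm.bimodality_check(uni, rng=rng)
    assert res.classification == "unimodal"
    bi = np.concatenate([rng.normal(0.1, 0.03, 400), rng.normal(0.9, 0.03, 400)])
    res2 = sm.bimodality_check(bi, rng=rng)
    assert res2.classification == "bimodal"
    assert res2.gmm_prefers_two


def test_migrant_mating_fraction():
    rec = pd.DataFrame(
        {
            "t": [1, 1, 1, 2, 2],
            "m1": [True, True, False, False, True],
            "m2": [True, False, False, False, True],
        }
    )
    res = sm.migrant_mating_fraction(rec, migration_fraction=0.01)
    assert res.fraction == pytest.approx(2 / 5)
    assert res.expected_random == pytest.approx(1e-4)
    by = res.by_generation.set_index("t")
    assert by.loc[1, "fraction"] == pytest.approx(1 / 3)
    assert by.loc[2, "fraction"] == pytest.approx(1 / 2)


def test_reproductive_success_sums_to_two_n():
    rec = pd.DataFrame({"i1": [0, 1, 2, 0], "i2": [1, 2, 3, 3]})
    parent_x = np.array([0.1, 0.4, 0.6, 0.9, 0.5])
    res = sm.reproductive_success_check(rec, parent_x)
    assert res.total_offspring_slots == 8
    np.testing.assert_array_equal(res.offspring_counts, [2, 2, 2, 2, 0])
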