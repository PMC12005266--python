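"""Hartigan's dip statistic for unimodality.

The dip of an empirical distribution function F is the smallest sup-norm
distance between F and any unimodal distribution function (convex
increasing up to a mode, concave increasing after it, jumps at the mode
allowed).  It is computed by the classical iterative scheme: shrink a
candidate modal interval using the greatest convex minorant (GCM) of the
lower ECDF and the least concave majorant (LCM) of the upper ECDF,
accumulating the sup deviations of the ECDF from the two fits outside the
modal interval, and stop when the remaining modal rise is covered.

The statistic is distribution-free under continuous sampling (invariant to
monotone transforms); p-values are obtained by Monte-Carlo sampling from
the uniform null, the standard reference distribution for the test.
"""

from __future__ import annotations

import numpy as np

try:  # Qhull is much faster than a Python monotone chain on large samples
    from scipy.spatial import ConvexHull, QhullError
except ImportError:  # pragma: no cover
    ConvexHull = None


def _chain(x: np.ndarray, y: np.ndarray, lower: bool) -> np.ndarray:
    """Monotone-chain hull over points sorted by x (strictly increasing):
    indices of the lower (convex minorant) or upper (concave majorant)
    polyline."""
    stack: list[int] = []
    for i in range(len(x)):
        while len(stack) >= 2:
            a, b = stack[-2], stack[-1]
            cross = (x[b] - x[a]) * (y[i] - y[a]) - (y[b] - y[a]) * (x[i] - x[a])
            if (cross <= 0) if lower else (cross >= 0):
                stack.pop()
            else:
                break
        stack.append(i)
    return np.asarray(stack, dtype=np.int64)


def _hull(x: np.ndarray, y: np.ndarray, lower: bool) -> np.ndarray:
    """Hull polyline indices; Qhull when possible, Python chain otherwise."""
    n = len(x)
    if n <= 2:
        return np.arange(n, dtype=np.int64)
    if ConvexHull is not None and n >= 5:
        try:
            hull = ConvexHull(np.column_stack([x, y]))
            v = np.asarray(hull.vertices, dtype=np.int64)
            # vertices are counter-clockwise; split at extreme-x vertices
            imin = int(np.argmin(x[v]))
            imax = int(np.argmax(x[v]))
            if lower:
                if imin <= imax:
                    chain = v[imin : imax + 1]
                else:
                    chain = np.concatenate([v[imin:], v[: imax + 1]])
            else:
                if imax <= imin:
                    chain = v[imax : imin + 1]
                else:
                    chain = np.concatenate([v[imax:], v[: imin + 1]])
                chain = chain[::-1]
            if np.all(np.diff(x[chain]) > 0):
                return chain
        except (QhullError, ValueError):
            pass
    return _chain(x, y, lower)


def dip_statistic(x: np.ndarray) -> float:
    """Dip statistic of a 1-d sample (0 for degenerate samples)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n < 2 or xs[0] == xs[-1]:
        return 0.0
    f_lo = np.arange(n) / n  # F(x_i^-)
    f_hi = np.arange(1, n + 1) / n  # F(x_i)

    low, high = 0, n - 1
    best = 0.0
    while True:
        idx = np.arange(low, high + 1)
        xv = xs[idx]
        # deduplicate tied x: convex minorant is bounded by the lowest
        # point at each x, the concave majorant by the highest
        first = np.concatenate([[True], np.diff(xv) > 0])
        last = np.concatenate([np.diff(xv) > 0, [True]])
        g_idx = idx[first]
        l_idx = idx[last]
        gt = g_idx[_hull(xs[g_idx], f_lo[g_idx], lower=True)]
        lt = l_idx[_hull(xs[l_idx], f_hi[l_idx], lower=False)]

        gcm = np.interp(xv, xs[gt], f_lo[gt])
        lcm = np.interp(xv, xs[lt], f_hi[lt])
        gap = lcm - gcm
        p = idx[int(np.argmax(gap))]
        d = float(gap[p - low])
        if d <= best + 1e-12:
            break
        ig = int(gt[np.searchsorted(gt, p, side="right") - 1])
        ih = int(lt[np.searchsorted(lt, p, side="left")])
        if ig == low and ih == high:
            best = max(best, d)
            break
        # sup deviation of the ECDF from the convex fit left of the modal
        # interval, and from the concave fit right of it
        if ig > low:
            seg = np.arange(low, ig + 1)
            dl = float(np.max(f_hi[seg] - gcm[seg - low]))
        else:
            dl = float(f_hi[low] - gcm[0])
        if ih < high:
            seg = np.arange(ih, high + 1)
            du = float(np.max(lcm[seg - low] - f_lo[seg]))
        else:
            du = float(lcm[high - low] - f_lo[high])
        best = max(best, dl, du)
        low, high = ig, ih
        if high - low < 1:
            d = float(f_hi[low] - f_lo[low])
            break
    return max(best, d) / 2.0


def dip_test(
    x: np.ndarray,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """(dip, p-value) with the Monte-Carlo uniform null."""
    if rng is None:
        rng = np.random.default_rng(0)
    d_obs = dip_statistic(x)
    n = len(np.asarray(x))
    boots = np.array(
        [dip_statistic(rng.random(n)) for _ in range(n_boot)]
    )
    p = (1.0 + np.sum(boots >= d_obs)) / (n_boot + 1.0)
    return d_obs, float(p)
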