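"""Deterministic generators of synthetic inputs.

Every analysis operation can be exercised without running the full engine:
exponential tract-length samples for the dating stack, mate-pair tables
with a requested Pearson correlation (Gaussian copula over a chosen
marginal), and two-cluster pair tables for the hexbin cluster detector.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tract_inference import TractLengthSample


@dataclass(frozen=True)
class FixtureSpec:
    generator: str
    params: tuple = ()
    seed: int = 0


def make_exponential_tracts(
    lam: float, n: int, seed: int = 0
) -> TractLengthSample:
    """n iid exponential tract lengths with rate ``lam`` per Morgan,
    reported in cM."""
    if lam <= 0 or n < 1:
        raise ValueError("need lam > 0 and n >= 1")
    rng = np.random.default_rng(seed)
    lengths_morgan = rng.exponential(scale=1.0 / lam, size=n)
    return TractLengthSample(lengths_morgan * 100.0)


def _records_from_pairs(x1: np.ndarray, x2: np.ndarray, t: int = 1) -> pd.DataFrame:
    n = len(x1)
    return pd.DataFrame(
        {
            "t": np.full(n, t, dtype=np.int32),
            "x1": x1,
            "x2": x2,
            "s1": np.zeros(n, dtype=np.int8),
            "s2": np.zeros(n, dtype=np.int8),
            "m1": np.zeros(n, dtype=bool),
            "m2": np.zeros(n, dtype=bool),
            "i1": np.arange(n, dtype=np.int64),
            "i2": np.arange(n, dtype=np.int64),
        }
    )


def _two_point_copula_rho(target_r: float) -> float:
    """Latent normal correlation giving Pearson correlation ``target_r``
    between two symmetric Bernoulli margins under a Gaussian copula.

    For p = 1/2 margins, corr = (4 P(Z1<0, Z2<0) - 1), solved for rho.
    """
    if target_r >= 1.0:
        return 1.0

    def f(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [0.0, 0.0], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return 4.0 * p11 - 1.0 - target_r

    return float(optimize.brentq(f, -0.999999, 0.999999, xtol=1e-10))


def make_mate_pairs(
    n: int,
    target_r: float,
    marginal: str = "two_point",
    seed: int = 0,
    loc: float = 0.5,
    scale: float = 0.1,
) -> pd.DataFrame:
    """Mate-pair table with Pearson correlation ``target_r``.

    marginal="two_point": x in {0, 1} with equal mass (the founder
    marginal); the latent-normal correlation is solved exactly so the
    empirical r converges to target_r.  marginal="truncnorm": normal
    (loc, scale) truncated to [0, 1]; the copula preserves target_r only
    approximately after the marginal transform (close for moderate r).
    """
    if not (0.0 <= target_r <= 1.0):
        raise ValueError("target_r must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if target_r == 1.0:
        if marginal == "two_point":
            x = (rng.random(n) < 0.5).astype(float)
        else:
            dist = stats.truncnorm((0 - loc) / scale, (1 - loc) / scale, loc, scale)
            x = dist.ppf(rng.random(n))
        return _records_from_pairs(x, x.copy())

    if marginal == "two_point":
        rho = _two_point_copula_rho(target_r)
    elif marginal == "truncnorm":
        rho = target_r
    else:
        raise ValueError(f"unknown marginal {marginal!r}")

    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = stats.norm.cdf(z)
    if marginal == "two_point":
        x1 = (u[:, 0] > 0.5).astype(float)
        x2 = (u[:, 1] > 0.5).astype(float)
    else:
        dist = stats.truncnorm((0 - loc) / scale, (1 - loc) / scale, loc, scale)
        x1 = np.clip(dist.ppf(u[:, 0]), 0.0, 1.0)
        x2 = np.clip(dist.ppf(u[:, 1]), 0.0, 1.0)
    return _records_from_pairs(x1, x2)


def make_two_cluster_pairs(
    n: int,
    centers: tuple[tuple[float, float], ...] = ((0.25, 0.25), (0.75, 0.75)),
    spread: float = 0.02,
    seed: int = 0,
    weights: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Mixture of bivariate Gaussian blobs on the diagonal (clipped to the
    unit square), exercising the hexbin cluster detector."""
    centers_arr = np.asarray(centers, dtype=float)
    if centers_arr.min() < 0 or centers_arr.max() > 1:
        raise ValueError("centers must lie in the unit square")
    k = len(centers_arr)
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    comp = rng.choice(k, size=n, p=w / w.sum())
    pts = centers_arr[comp] + rng.normal(0.0, spread, size=(n, 2))
    pts = np.clip(pts, 0.0, 1.0)
    return _records_from_pairs(pts[:, 0], pts[:, 1])
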