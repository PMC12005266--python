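"""Mate-choice weight functions and the common bias parameter alpha.

Four mating-weight functions psi_{i,j} are implemented on a common bias
parameter alpha >= 1: at the moment of population contact (all x in
{0, 1}), every model makes an individual alpha times more likely to choose
a mate from its own source population than from the other one, so all
models produce the same first-generation mate-pair correlation
r = (alpha - 1)/(alpha + 1).

Models
------
stationary
    psi = exp(-c |x_i - x_j|), c = ln(alpha); the decay rate is fixed over
    time ("like-with-like" preference).
increasing
    psi = exp(-(c / sigma2_x(t)) |x_i - x_j|) with c = ln(alpha) *
    sigma2_x(0): the effective decay rate is rescaled each generation by
    the current population variance in ancestry, so choosiness increases
    as the population homogenises.
broad
    psi is the normal density N(x_i, sigma2) evaluated at x_j, with
    sigma2 = 1 / (2 ln alpha) so that the own/cross weight ratio at
    |dx| = 1 equals alpha.
social_group
    psi = 1 - 1/(alpha+1) for same-group pairs, 1/(alpha+1) for
    cross-group pairs (binary, non-genetic group label).

alpha = 1 reduces every model to uniform weights (random mating).
Weights are unnormalised sampling masses per mating event; only ratios
matter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

MODELS = ("random", "stationary", "increasing", "broad", "social_group")

#: variance of global ancestry among founders under equal admixture
#: (Bernoulli(1/2) variance)
FOUNDER_VARIANCE = 0.25


class AlphaRangeError(ValueError):
    """alpha < 1 (negative assortment) is out of scope."""


@dataclass(frozen=True)
class MateChoiceSpec:
    """A mate-choice model with all constants derived from alpha.

    Attributes
    ----------
    model
        One of ``random``, ``stationary``, ``increasing``, ``broad``,
        ``social_group``.
    alpha
        Bias strength; alpha >= 1, alpha = 1 is random mating.
    c
        Exponential decay constant (stationary: ln(alpha); increasing:
        ln(alpha) * founder_variance, rescaled per generation).
    sigma2
        Gaussian variance (broad model only), 1 / (2 ln alpha).
    founder_variance
        sigma2_x(0) used to calibrate the increasing model.
    """

    model: str
    alpha: float
    c: float | None = None
    sigma2: float | None = None
    founder_variance: float = FOUNDER_VARIANCE

    @property
    def is_random(self) -> bool:
        return self.model == "random" or self.alpha == 1.0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "alpha": self.alpha,
            "c": self.c,
            "sigma2": self.sigma2,
            "founder_variance": self.founder_variance,
        }


def calibrate(
    model: str, alpha: float, founder_variance: float = FOUNDER_VARIANCE
) -> MateChoiceSpec:
    """Derive the per-model constants putting all models on a common alpha.

    The calibration makes the own-population vs cross-population selection
    weight ratio equal alpha at the moment of contact under every model:
    stationary c = ln(alpha); increasing c = ln(alpha) * sigma2_x(0) (so
    the rescaled rate c / sigma2_x(0) is ln(alpha) in the first
    generation); broad sigma2 = 1/(2 ln alpha); the social-group weights
    already have same/different ratio alpha.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if alpha < 1:
        raise AlphaRangeError(f"alpha must be >= 1 (got {alpha})")
    if model == "random" or alpha == 1.0:
        return MateChoiceSpec("random" if model == "random" else model, alpha,
                              founder_variance=founder_variance)
    if model == "stationary":
        return MateChoiceSpec(model, alpha, c=math.log(alpha),
                              founder_variance=founder_variance)
    if model == "increasing":
        return MateChoiceSpec(model, alpha, c=math.log(alpha) * founder_variance,
                              founder_variance=founder_variance)
    if model == "broad":
        return MateChoiceSpec(model, alpha, sigma2=1.0 / (2.0 * math.log(alpha)),
                              founder_variance=founder_variance)
    return MateChoiceSpec(model, alpha, founder_variance=founder_variance)


# ---------------------------------------------------------------------------
# Weight functions (scalar or numpy-broadcasting)
# ---------------------------------------------------------------------------


def weight_stationary(x_i, x_j, spec: MateChoiceSpec):
    """exp(-c |x_i - x_j|); symmetric, maximal (=1) iff x_i == x_j."""
    if spec.is_random:
        return np.ones_like(np.broadcast_arrays(np.asarray(x_i, float),
                                                np.asarray(x_j, float))[0])
    return np.exp(-spec.c * np.abs(np.asarray(x_i, float) - np.asarray(x_j, float)))


def weight_increasing(x_i, x_j, spec: MateChoiceSpec, current_variance: float):
    """exp(-(c / sigma2_x(t)) |x_i - x_j|).

    The effective decay rate grows as the population variance shrinks
    (increasing choosiness).  With ``current_variance`` equal to the
    founder variance the own/cross ratio is exactly alpha.  A degenerate
    pool (variance 0) falls back to uniform weights.
    """
    dx = np.abs(np.asarray(x_i, float) - np.asarray(x_j, float))
    if spec.is_random:
        return np.ones_like(dx)
    if current_variance <= 0:
        logger.warning(
            "increasing-preference model: sigma2_x(t)=0, all mates identical; "
            "falling back to uniform weights"
        )
        return np.ones_like(dx)
    return np.exp(-(spec.c / current_variance) * dx)


def weight_broad(x_i, x_j, spec: MateChoiceSpec):
    """Normal density at x_j with mean x_i and variance sigma2."""
    dx = np.asarray(x_i, float) - np.asarray(x_j, float)
    if spec.is_random:
        return np.ones_like(dx)
    s2 = spec.sigma2
    return np.exp(-(dx**2) / (2.0 * s2)) / math.sqrt(2.0 * math.pi * s2)


def weight_social(s_i, s_j, spec: MateChoiceSpec):
    """1 - 1/(alpha+1) if same group else 1/(alpha+1); the two sum to 1."""
    same = np.asarray(s_i) == np.asarray(s_j)
    w_cross = 1.0 / (spec.alpha + 1.0)
    return np.where(same, 1.0 - w_cross, w_cross)


def log_weights(
    focal_x: np.ndarray,
    pool_x: np.ndarray,
    spec: MateChoiceSpec,
    current_variance: float | None = None,
) -> np.ndarray:
    """Log sampling weights for the ancestry-similarity models,
    broadcasting focal (n_f, 1) against pool (n_p,).  Used by the engine's
    vectorised sampler; absolute scale is irrelevant."""
    dx = np.abs(focal_x[:, None] - pool_x[None, :])
    if spec.is_random:
        return np.zeros_like(dx)
    if spec.model == "stationary":
        return -spec.c * dx
    if spec.model == "increasing":
        if current_variance is None:
            raise ValueError("increasing model needs the current variance")
        if current_variance <= 0:
            return np.zeros_like(dx)
        return -(spec.c / current_variance) * dx
    if spec.model == "broad":
        return -(dx**2) / (2.0 * spec.sigma2)
    raise ValueError(f"log_weights undefined for model {spec.model!r}")


# ---------------------------------------------------------------------------
# Reference per-event sampler
# ---------------------------------------------------------------------------


def pair_weight(
    x_i: float,
    x_j: float,
    s_i: int,
    s_j: int,
    spec: MateChoiceSpec,
    current_variance: float | None = None,
) -> float:
    """psi for one ordered pair under any model."""
    if spec.is_random:
        return 1.0
    if spec.model == "stationary":
        return float(weight_stationary(x_i, x_j, spec))
    if spec.model == "increasing":
        return float(weight_increasing(x_i, x_j, spec, current_variance))
    if spec.model == "broad":
        return float(weight_broad(x_i, x_j, spec))
    return float(weight_social(s_i, s_j, spec))


def sample_mate(
    focal: int,
    pool_x: np.ndarray,
    pool_group: np.ndarray,
    spec: MateChoiceSpec,
    rng: np.random.Generator,
    current_variance: float | None = None,
) -> int:
    """One mate for ``focal``: an index != focal sampled with probability
    proportional to its psi weight over all non-focal pool members.

    This is the single-event reference path; the engine uses an exact
    vectorised equivalent.  Selfing is explicitly prohibited.
    """
    n = len(pool_x)
    if n < 2:
        raise ValueError("pool must contain at least two individuals")
    if spec.model == "increasing" and current_variance is None:
        current_variance = float(np.var(pool_x))
    w = np.array(
        [
            pair_weight(pool_x[focal], pool_x[j], pool_group[focal],
                        pool_group[j], spec, current_variance)
            for j in range(n)
        ]
    )
    w[focal] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("all mating weights are zero")
    return int(rng.choice(n, p=w / total))
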