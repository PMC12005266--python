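"""Per-generation statistics linking mate-choice mechanism to outcome.

Implements the analysis stack applied to simulated mating records and
populations: the mate-pair Pearson correlation r(x_i, x_j) and its
permutation null, the variance in global ancestry across individuals
sigma2_x(t), the distribution of mate differences dx = |x_i - x_j|,
hexagonal-bin mating structure (with a connected-cluster count),
a bimodality check on the ancestry distribution (Hartigan's dip test with
a Gaussian-mixture BIC cross-check), migrant-mating prevalence under
continuous migration, and a reproductive-success diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dip import dip_statistic, dip_test


def _pair_columns(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["x1"].to_numpy(float), records["x2"].to_numpy(float)
    x1, x2 = records
    return np.asarray(x1, float), np.asarray(x2, float)


def ancestry_variance(x: np.ndarray) -> float:
    """Population variance (divide by N) of global ancestry proportion."""
    return float(np.var(np.asarray(x, dtype=float)))


def mate_correlation(records, symmetrize: bool = False) -> float:
    """Pearson correlation of (x_parent1, x_parent2) over ordered pairs.

    Returns NaN when either column is constant (the correlation is
    undefined once sigma2_x(t) = 0).  With ``symmetrize=True`` each pair is
    also counted reversed; parent roles are exchangeable so the two
    variants agree within sampling error.
    """
    x1, x2 = _pair_columns(records)
    if len(x1) < 2:
        return float("nan")
    if symmetrize:
        x1, x2 = np.concatenate([x1, x2]), np.concatenate([x2, x1])
    if np.var(x1) == 0 or np.var(x2) == 0:
        return float("nan")
    return float(np.corrcoef(x1, x2)[0, 1])


@dataclass
class PermutationResult:
    """One-sided permutation test for positive ancestry assortment."""

    r_observed: float
    permuted: np.ndarray
    empirical_p: float
    n_permutations: int


def permutation_test(
    records, n_permutations: int = 1000, rng: np.random.Generator | None = None
) -> PermutationResult:
    """Permute the parent-2 column and recompute r.

    ``empirical_p = (1 + #{r_perm >= r_obs}) / (B + 1)`` — one-sided
    (positive assortment is the hypothesis), non-strict tail, add-one
    estimator so p is never zero.  Constant-x records yield a NaN sentinel.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x1, x2 = _pair_columns(records)
    r_obs = mate_correlation((x1, x2))
    if np.isnan(r_obs):
        return PermutationResult(float("nan"), np.empty(0), float("nan"), n_permutations)
    perm = np.empty(n_permutations)
    for b in range(n_permutations):
        perm[b] = np.corrcoef(x1, rng.permutation(x2))[0, 1]
    p = (1.0 + np.sum(perm >= r_obs)) / (n_permutations + 1.0)
    return PermutationResult(r_obs, perm, float(p), n_permutations)


@dataclass
class DeltaXSummary:
    """Distribution of dx = |x_parent1 - x_parent2| over mate pairs."""

    quantiles: dict[float, float]
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    mean: float
    values: np.ndarray = field(repr=False)


def delta_x_distribution(records, n_bins: int = 40) -> DeltaXSummary:
    """Quantiles and histogram of the absolute mate difference in global
    ancestry proportion ("hurricane plot" support)."""
    x1, x2 = _pair_columns(records)
    dx = np.abs(x1 - x2)
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    counts, edges = np.histogram(dx, bins=n_bins, range=(0.0, 1.0))
    return DeltaXSummary(
        {q: float(np.quantile(dx, q)) for q in qs},
        counts,
        edges,
        float(dx.mean()),
        dx,
    )


@dataclass
class HexbinResult:
    """Hexagonal-bin density of mate pairs on the (x_i, x_j) unit square."""

    centers: np.ndarray  # (n_cells, 2) hexagon centers
    counts: np.ndarray  # raw counts per cell
    scaled: np.ndarray  # counts / max (max cell = 1)
    n_clusters: int  # connected high-density regions
    density_threshold: float
    bin_width: float


def hexbin_counts(
    records, bin_width: float = 0.025, density_threshold: float = 0.2
) -> HexbinResult:
    """Hexagonal tessellation of the unit square with the given cell width,
    counts scaled so the maximum cell is 1, plus the number of connected
    high-density regions (cells with scaled density >= threshold,
    connectivity over adjacent hexagons)."""
    from matplotlib.figure import Figure
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree
    from scipy.sparse import csr_matrix

    x1, x2 = _pair_columns(records)
    gridsize = int(round(1.0 / bin_width))
    fig = Figure()
    ax = fig.add_subplot()
    hb = ax.hexbin(x1, x2, gridsize=gridsize, extent=(0, 1, 0, 1))
    counts = np.asarray(hb.get_array(), dtype=float)
    centers = np.asarray(hb.get_offsets(), dtype=float)

    max_count = counts.max() if counts.size else 0.0
    scaled = counts / max_count if max_count > 0 else counts
    high = scaled >= density_threshold
    n_clusters = 0
    if high.any():
        pts = centers[high]
        if len(pts) == 1:
            n_clusters = 1
        else:
            # adjacent hexagon centers are the closest center pairs; the
            # next-nearest lattice distance is ~sqrt(3) farther away
            tree = cKDTree(centers)
            dists, _ = tree.query(centers[:1], k=min(7, len(centers)))
            nn = np.min(dists[0][dists[0] > 0]) if len(centers) > 1 else 1.0
            sub = cKDTree(pts)
            pairs = sub.query_pairs(r=1.4 * nn, output_type="ndarray")
            m = len(pts)
            graph = csr_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
            )
            n_clusters, _ = connected_components(graph, directed=False)
    return HexbinResult(centers, counts, scaled, int(n_clusters),
                        density_threshold, bin_width)


@dataclass
class BimodalityResult:
    """Classification of the ancestry-proportion distribution."""

    classification: str  # 'unimodal' or 'bimodal'
    dip: float
    p_value: float
    significance: float
    gmm_bic_1: float
    gmm_bic_2: float
    gmm_prefers_two: bool


def bimodality_check(
    x: np.ndarray,
    rng: np.random.Generator | None = None,
    n_boot: int = 200,
    significance: float = 0.01,
) -> BimodalityResult:
    """Dip test (Monte-Carlo uniform null) as the primary classifier, with
    a 1- vs 2-component Gaussian-mixture BIC comparison as a cross-check.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    dip, p = dip_test(x, n_boot=n_boot, rng=rng)
    data = x.reshape(-1, 1)
    seed = int(rng.integers(2**31 - 1))
    bic = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=2)
        gm.fit(data)
        bic.append(float(gm.bic(data)))
    return BimodalityResult(
        "bimodal" if p < significance else "unimodal",
        dip,
        p,
        significance,
        bic[0],
        bic[1],
        bic[1] < bic[0],
    )


@dataclass
class MigrantMatingSummary:
    fraction: float  # mating events with both parents migrants
    expected_random: float | None  # migration_fraction ** 2
    by_generation: pd.DataFrame  # columns t, fraction, n


def migrant_mating_fraction(
    records: pd.DataFrame, migration_fraction: float | None = None
) -> MigrantMatingSummary:
    """Proportion of mating events where both parents are migrants, overall
    and per generation, with the random-mating expectation
    migration_fraction**2 for reference."""
    both = records["m1"].to_numpy(bool) & records["m2"].to_numpy(bool)
    t = records["t"].to_numpy()
    by_gen = (
        pd.DataFrame({"t": t, "both": both})
        .groupby("t")["both"]
        .agg(fraction="mean", n="size")
        .reset_index()
    )
    expected = migration_fraction**2 if migration_fraction is not None else None
    return MigrantMatingSummary(float(both.mean()) if len(both) else 0.0,
                                expected, by_gen)


@dataclass
class ReproductiveSuccessResult:
    offspring_counts: np.ndarray  # per parental-pool individual
    correlation: float  # Pearson r between x and offspring count
    total_offspring_slots: int  # == 2 * n_offspring


def reproductive_success_check(
    generation_records: pd.DataFrame, parent_x: np.ndarray
) -> ReproductiveSuccessResult:
    """Association between global ancestry proportion and realised
    offspring number in the parental pool (parent-1 draws are uniform, so
    only parent-2 selection can bias this)."""
    n = len(parent_x)
    i1 = generation_records["i1"].to_numpy()
    i2 = generation_records["i2"].to_numpy()
    counts = np.bincount(i1, minlength=n) + np.bincount(i2, minlength=n)
    if np.var(parent_x) == 0 or np.var(counts) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(parent_x, counts)[0, 1])
    return ReproductiveSuccessResult(counts, r, int(counts.sum()))


__all__ = [
    "ancestry_variance",
    "mate_correlation",
    "permutation_test",
    "PermutationResult",
    "delta_x_distribution",
    "DeltaXSummary",
    "hexbin_counts",
    "HexbinResult",
    "bimodality_check",
    "BimodalityResult",
    "migrant_mating_fraction",
    "MigrantMatingSummary",
    "reproductive_success_check",
    "ReproductiveSuccessResult",
    "dip_statistic",
    "dip_test",
]
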