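"""Non-overlapping-generation population loop.

Founding (single admixture pulse, equal contributions by default), N
mating events per generation (parent 1 uniform with replacement, parent 2
proportional to the mate-choice weight, selfing prohibited, one child per
event), social-group inheritance from parent 1, optional continuous
migration, and per-generation recording of mate pairs and summary
statistics.

Generation numbering: founders are t=0, the first post-admixture offspring
generation is t=1.  Simulations are deterministic given (seed, replicate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import (
    GenomeMap,
    PopulationGenomes,
    combine_gametes,
    sample_gametes,
)
from .mate_choice import MateChoiceSpec, calibrate, log_weights

logger = logging.getLogger(__name__)

SCENARIOS = ("single_pulse", "continuous_migration")

RECORD_COLUMNS = ["t", "x1", "x2", "s1", "s2", "m1", "m2", "i1", "i2"]


@dataclass(frozen=True)
class SimConfig:
    """Run configuration.

    Attributes
    ----------
    model, alpha
        Mate-choice model and common bias strength (see
        :mod:`assortmate.mate_choice`).
    N
        Census size per generation.
    generations
        Number of post-admixture generations T to simulate.
    scenario
        ``single_pulse`` (default) or ``continuous_migration``.
    migration_fraction
        Fraction of each generation replaced by unadmixed migrants
        (continuous-migration scenario only).
    founding_prop
        Founding proportion m from source population 1.
    seed, replicate
        Seed the simulation stream; the replicate index offsets the seed
        deterministically.
    record_tracts_at
        Generations at which pooled tract-length samples (cM) are kept.
    pool_subsample
        Optional candidate-pool size per mating event (speed option; exact
        whole-population weighting when None, as in all shipped analyses).
    migrants_mate_on_arrival
        When False, migrants are excluded from the parental pool in the
        generation they arrive.
    """

    model: str
    alpha: float
    N: int = 10_000
    generations: int = 20
    scenario: str = "single_pulse"
    migration_fraction: float = 0.01
    founding_prop: float = 0.5
    seed: int = 0
    replicate: int = 0
    genome_map: GenomeMap | None = None
    record_tracts_at: tuple[int, ...] = ()
    pool_subsample: int | None = None
    migrants_mate_on_arrival: bool = True

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not (0 <= self.migration_fraction < 1):
            raise ValueError("migration_fraction must be in [0, 1)")
        if not (0 < self.founding_prop < 1):
            raise ValueError("founding_prop must be in (0, 1)")

    @property
    def gmap(self) -> GenomeMap:
        return self.genome_map if self.genome_map is not None else GenomeMap.default_human()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(self.replicate)])

    def spec(self) -> MateChoiceSpec:
        return calibrate(self.model, self.alpha)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "alpha": self.alpha,
            "N": self.N,
            "generations": self.generations,
            "scenario": self.scenario,
            "migration_fraction": self.migration_fraction,
            "founding_prop": self.founding_prop,
            "seed": self.seed,
            "replicate": self.replicate,
            "record_tracts_at": list(self.record_tracts_at),
            "pool_subsample": self.pool_subsample,
            "migrants_mate_on_arrival": self.migrants_mate_on_arrival,
            "genome": {
                "chrom_lengths_bp": list(self.gmap.chrom_lengths_bp),
                "recomb_rate": self.gmap.recomb_rate,
            },
        }


@dataclass
class Population:
    """One generation: genomes plus per-individual state."""

    genomes: PopulationGenomes
    x: np.ndarray  # global ancestry proportion, float in [0, 1]
    group: np.ndarray  # int8: 0 = group A, 1 = group B
    is_migrant: np.ndarray  # arrived as an unadmixed migrant this generation

    @property
    def size(self) -> int:
        return len(self.x)


@dataclass
class SimulationResult:
    config: SimConfig
    summaries: pd.DataFrame
    records: pd.DataFrame
    tract_samples: dict[int, np.ndarray] = field(default_factory=dict)
    final_population: Population | None = None


def _split_counts(n: int, prop: float) -> tuple[int, int]:
    """Floor both shares, remainder to source 1 (logged when n*prop is not
    integral)."""
    n1 = int(np.floor(n * prop))
    n2 = int(np.floor(n * (1.0 - prop)))
    rem = n - n1 - n2
    if rem:
        logger.info("rounding %d unassigned founders/migrants to source 1", rem)
        n1 += rem
    return n1, n2


def init_population(config: SimConfig) -> Population:
    """Generation-0 founders: unadmixed, source 1 -> x=1/group A, source 2
    -> x=0/group B, single full-chromosome tracts."""
    n1, n2 = _split_counts(config.N, config.founding_prop)
    sources = np.concatenate([np.ones(n1, dtype=np.int8), np.full(n2, 2, dtype=np.int8)])
    genomes = PopulationGenomes.from_founder_sources(sources, config.gmap)
    x = (sources == 1).astype(float)
    group = (sources != 1).astype(np.int8)  # A=0 for source 1, B=1 for source 2
    return Population(genomes, x, group, np.ones(config.N, dtype=bool))


# ---------------------------------------------------------------------------
# Vectorised mate sampling
# ---------------------------------------------------------------------------

_CHUNK = 512


def _sample_partners(
    x: np.ndarray,
    group: np.ndarray,
    p1: np.ndarray,
    spec: MateChoiceSpec,
    rng: np.random.Generator,
    current_variance: float | None,
    pool_subsample: int | None = None,
) -> np.ndarray:
    """Parent-2 indices: for each focal in ``p1``, one index != focal drawn
    with probability proportional to its psi weight over all non-focal pool
    members (exact; Gumbel-max on log-weights for the ancestry models)."""
    n = len(x)
    m = len(p1)
    if spec.is_random:
        return (p1 + 1 + rng.integers(0, n - 1, size=m)) % n

    if spec.model == "social_group":
        return _sample_partners_social(group, p1, spec, rng)

    out = np.empty(m, dtype=np.int64)
    if pool_subsample is not None and pool_subsample < n:
        k = pool_subsample
        cand = rng.integers(0, n, size=(m, k))
        lw = log_weights(x[p1], x, spec, current_variance)[
            np.arange(m)[:, None], cand
        ]
        lw[cand == p1[:, None]] = -np.inf
        g = rng.gumbel(0.0, 1.0, size=lw.shape)
        best = np.argmax(lw + g, axis=1)
        out = cand[np.arange(m), best]
        bad = out == p1
        out[bad] = (p1[bad] + 1) % n
        return out

    for s in range(0, m, _CHUNK):
        f = p1[s : s + _CHUNK]
        lw = log_weights(x[f], x, spec, current_variance)
        lw[np.arange(len(f)), f] = -np.inf
        lw += rng.gumbel(0.0, 1.0, size=lw.shape)
        out[s : s + _CHUNK] = np.argmax(lw, axis=1)
    return out


def _sample_partners_social(
    group: np.ndarray,
    p1: np.ndarray,
    spec: MateChoiceSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact two-stage sampler for the social-group model: pick same vs
    cross group with the aggregated weight mass, then uniform within."""
    n = len(group)
    m = len(p1)
    idx_a = np.flatnonzero(group == 0)
    idx_b = np.flatnonzero(group == 1)
    n_a, n_b = len(idx_a), len(idx_b)
    rank = np.empty(n, dtype=np.int64)
    rank[idx_a] = np.arange(n_a)
    rank[idx_b] = np.arange(n_b)

    w_cross = 1.0 / (spec.alpha + 1.0)
    w_same = 1.0 - w_cross
    gf = group[p1]
    n_same = np.where(gf == 0, n_a, n_b)
    n_diff = np.where(gf == 0, n_b, n_a)
    mass_same = w_same * (n_same - 1)
    mass_diff = w_cross * n_diff
    total = mass_same + mass_diff
    choose_same = rng.random(m) * total < mass_same

    out = np.empty(m, dtype=np.int64)
    r_same = rng.integers(0, np.maximum(n_same - 1, 1), size=m)
    r_same = r_same + (r_same >= rank[p1])
    r_diff = rng.integers(0, np.maximum(n_diff, 1), size=m)

    sel = choose_same & (gf == 0)
    out[sel] = idx_a[r_same[sel]]
    sel = choose_same & (gf == 1)
    out[sel] = idx_b[r_same[sel]]
    sel = ~choose_same & (gf == 0)
    out[sel] = idx_b[r_diff[sel]]
    sel = ~choose_same & (gf == 1)
    out[sel] = idx_a[r_diff[sel]]
    return out


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------


def run_generation(
    pop: Population,
    spec: MateChoiceSpec,
    config: SimConfig,
    rng: np.random.Generator,
    t: int,
) -> tuple[Population, pd.DataFrame]:
    """One generation of N independent mating events.

    Parent 1 is uniform with replacement; parent 2 is drawn proportional to
    psi over the non-focal pool; the child receives one recombinant gamete
    from each parent and parent 1's social group.  Returns the offspring
    population and the mating record (one row per offspring).
    """
    n_off = config.N
    if config.migrants_mate_on_arrival or not pop.is_migrant.any():
        pool = None
        pool_x, pool_group = pop.x, pop.group
    else:
        pool = np.flatnonzero(~pop.is_migrant)
        if len(pool) < 2:
            # everyone is a fresh arrival (the founding generation):
            # exclusion would empty the pool, so it does not apply
            pool = None
            pool_x, pool_group = pop.x, pop.group
        else:
            pool_x, pool_group = pop.x[pool], pop.group[pool]

    current_variance = None
    if spec.model == "increasing":
        current_variance = float(np.var(pool_x))
        if current_variance <= 0 and not spec.is_random:
            logger.warning(
                "generation %d: sigma2_x=0, increasing model degenerates to "
                "uniform weights",
                t,
            )

    p1_local = rng.integers(0, len(pool_x), size=n_off)
    p2_local = _sample_partners(
        pool_x, pool_group, p1_local, spec, rng, current_variance,
        config.pool_subsample,
    )
    if pool is None:
        p1, p2 = p1_local, p2_local
    else:
        p1, p2 = pool[p1_local], pool[p2_local]

    gam1 = sample_gametes(pop.genomes, p1, rng)
    gam2 = sample_gametes(pop.genomes, p2, rng)
    genomes = combine_gametes(pop.genomes.gmap, gam1, gam2)
    x = genomes.global_ancestry()
    group = pop.group[p1].copy()
    offspring = Population(genomes, x, group, np.zeros(n_off, dtype=bool))

    records = pd.DataFrame(
        {
            "t": np.full(n_off, t, dtype=np.int32),
            "x1": pop.x[p1],
            "x2": pop.x[p2],
            "s1": pop.group[p1],
            "s2": pop.group[p2],
            "m1": pop.is_migrant[p1],
            "m2": pop.is_migrant[p2],
            "i1": p1.astype(np.int64),
            "i2": p2.astype(np.int64),
        }
    )
    return offspring, records


def apply_migration(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> Population:
    """Replace floor(migration_fraction * N) uniformly chosen individuals
    with unadmixed migrants, half per source (remainder to source 1).

    Replacements carry the migrant flag for this generation only; source-1
    migrants get x=1/group A, source-2 migrants x=0/group B.
    """
    n = pop.size
    n_mig = int(np.floor(config.migration_fraction * n))
    pop.is_migrant = np.zeros(n, dtype=bool)
    if n_mig == 0:
        return pop
    idx = rng.choice(n, size=n_mig, replace=False)
    n1, _ = _split_counts(n_mig, 0.5)
    src1 = idx[:n1]
    src2 = idx[n1:]

    rows = np.empty(2 * n_mig, dtype=np.int64)
    rows[0::2] = 2 * idx
    rows[1::2] = 2 * idx + 1
    row_is_src1 = np.empty(2 * n_mig, dtype=bool)
    row_is_src1[0::2] = row_is_src1[1::2] = np.concatenate(
        [np.ones(n1, dtype=bool), np.zeros(n_mig - n1, dtype=bool)]
    )
    for ch in pop.genomes.chroms:
        counts = ch.counts()
        rowflag = np.zeros(ch.n_rows, dtype=bool)
        rowflag[rows] = True
        if len(ch.pos):
            elem_rows = np.repeat(np.arange(ch.n_rows), counts)
            ch.pos = ch.pos[~rowflag[elem_rows]]
        counts = counts.copy()
        counts[rows] = 0
        ch.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        ch.source1_at_0[rows] = row_is_src1

    pop.x[src1] = 1.0
    pop.x[src2] = 0.0
    pop.group[src1] = 0
    pop.group[src2] = 1
    pop.is_migrant[idx] = True
    return pop


def _summarize(pop: Population, t: int, records: pd.DataFrame | None) -> dict:
    """One GenerationSummary row."""
    from . import summaries as sm

    lengths_cm = pop.genomes.gmap.bp_to_cm(pop.genomes.tract_lengths_bp())
    row = {
        "t": t,
        "r_mates": np.nan,
        "sigma2_x": sm.ancestry_variance(pop.x),
        "mean_x": float(np.mean(pop.x)),
        "mean_tract_cm": float(np.mean(lengths_cm)),
        "median_tract_cm": float(np.median(lengths_cm)),
        "p95_tract_cm": float(np.percentile(lengths_cm, 95)),
        "frac_migrant_matings": np.nan,
        "frac_group_a": float(np.mean(pop.group == 0)),
        "n_pairs": 0,
    }
    if records is not None:
        row["r_mates"] = sm.mate_correlation(records)
        row["frac_migrant_matings"] = float(
            np.mean(records["m1"].to_numpy() & records["m2"].to_numpy())
        )
        row["n_pairs"] = len(records)
    return row


def run_simulation(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    keep_records: bool = True,
    keep_final_population: bool = True,
) -> SimulationResult:
    """Run the full loop and collect per-generation summaries, mating
    records and optional tract-length samples.

    Deterministic given (seed, replicate): the same config produces
    byte-identical tables.
    """
    if rng is None:
        rng = config.rng()
    spec = config.spec()
    pop = init_population(config)
    summaries_rows = [_summarize(pop, 0, None)]
    all_records: list[pd.DataFrame] = []
    tract_samples: dict[int, np.ndarray] = {}
    if 0 in config.record_tracts_at:
        tract_samples[0] = np.asarray(
            config.gmap.bp_to_cm(pop.genomes.tract_lengths_bp())
        )

    for t in range(1, config.generations + 1):
        pop, records = run_generation(pop, spec, config, rng, t)
        if config.scenario == "continuous_migration":
            pop = apply_migration(pop, config, rng)
        summaries_rows.append(_summarize(pop, t, records))
        if keep_records:
            all_records.append(records)
        if t in config.record_tracts_at:
            tract_samples[t] = np.asarray(
                config.gmap.bp_to_cm(pop.genomes.tract_lengths_bp())
            )

    summaries_df = pd.DataFrame(summaries_rows)
    records_df = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else pd.DataFrame(columns=RECORD_COLUMNS)
    )
    return SimulationResult(
        config,
        summaries_df,
        records_df,
        tract_samples,
        pop if keep_final_population else None,
    )
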