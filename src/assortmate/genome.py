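"""Tract-based diploid genomes and meiosis with crossovers.

Genomes are represented as source-labeled local-ancestry tracts over 22
independently segregating chromosomes.  Two layers are provided:

* a small object layer (:class:`Tract`, :class:`Haplotype`,
  :class:`Individual`) with a straightforward per-chromosome meiosis,
  convenient for small examples and used as the reference implementation
  in the test suite;
* a flat, vectorised population layer (:class:`PopulationGenomes`) used by
  the simulation engine, storing each haplotype-chromosome as a sorted
  array of ancestry switch points plus the source at position 0.

Because there are only two source populations, merged tracts on a
haplotype strictly alternate sources, so switch points plus the leading
source determine the haplotype completely.

Coordinates are 0-based half-open bp intervals.  Crossover counts are
Poisson with mean ``chrom_length_bp * recomb_rate`` (no interference),
positions uniform, floored to bp; duplicate positions within one meiosis
cancel pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

# GRCh38 autosome lengths (bp), chr1..chr22.
_GRCH38_AUTOSOMES = np.array(
    [
        248956422, 242193529, 198295559, 190214555, 181538259, 170805979,
        159345973, 145138636, 138394717, 133797422, 135086622, 133275309,
        114364328, 107043718, 101991189, 90338345, 83257441, 80373285,
        58617616, 64444167, 46709983, 50818468,
    ],
    dtype=np.int64,
)

DEFAULT_TOTAL_BP = 2_880_000_000
DEFAULT_RECOMB_RATE = 1e-8  # Morgan per bp


class GenomeMapError(ValueError):
    """Structural error in a genome map or tract tiling."""


@dataclass(frozen=True)
class GenomeMap:
    """22 chromosome lengths (bp) and a uniform per-bp crossover rate.

    Parameters
    ----------
    chrom_lengths_bp
        Lengths of the 22 autosomes in bp; all positive.
    recomb_rate
        Uniform crossover rate in Morgan/bp (default 1e-8, i.e. 1 cM/Mb).
    """

    chrom_lengths_bp: tuple[int, ...]
    recomb_rate: float = DEFAULT_RECOMB_RATE

    def __post_init__(self) -> None:
        if len(self.chrom_lengths_bp) != 22:
            raise GenomeMapError(
                f"expected 22 chromosomes, got {len(self.chrom_lengths_bp)}"
            )
        if any(length <= 0 for length in self.chrom_lengths_bp):
            raise GenomeMapError("all chromosome lengths must be positive")
        if self.recomb_rate < 0:
            raise GenomeMapError("recombination rate must be non-negative")
        object.__setattr__(
            self, "chrom_lengths_bp", tuple(int(v) for v in self.chrom_lengths_bp)
        )

    @property
    def total_length_bp(self) -> int:
        """Total diploid-haploid genome size L in bp."""
        return int(sum(self.chrom_lengths_bp))

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_bp)

    def bp_to_cm(self, bp) -> np.ndarray | float:
        """Convert physical length to genetic length in cM."""
        return np.asarray(bp, dtype=float) * self.recomb_rate * 100.0

    @classmethod
    def default_human(cls) -> "GenomeMap":
        """Human-autosome-shaped map: GRCh38 autosome lengths rescaled to
        sum exactly 2.88 Gb, uniform rate 1e-8 Morgan/bp."""
        scaled = np.floor(
            _GRCH38_AUTOSOMES * (DEFAULT_TOTAL_BP / _GRCH38_AUTOSOMES.sum())
        ).astype(np.int64)
        scaled[0] += DEFAULT_TOTAL_BP - scaled.sum()
        return cls(tuple(int(v) for v in scaled), DEFAULT_RECOMB_RATE)


class Tract(NamedTuple):
    """A maximal single-source segment on one haplotype."""

    chrom: int
    start_bp: int
    end_bp: int
    source: int  # population label, 1 or 2


# ---------------------------------------------------------------------------
# Object layer (reference implementation)
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """Per-chromosome ordered tract lists tiling [0, chrom_length)."""

    tracts: list[list[Tract]]

    @classmethod
    def unadmixed(cls, source: int, gmap: GenomeMap) -> "Haplotype":
        return cls(
            [
                [Tract(c, 0, L, source)]
                for c, L in enumerate(gmap.chrom_lengths_bp)
            ]
        )

    def validate(self, gmap: GenomeMap) -> None:
        """Raise GenomeMapError unless tracts tile each chromosome exactly."""
        if len(self.tracts) != gmap.n_chromosomes:
            raise GenomeMapError("wrong number of chromosomes")
        for c, (chrom_tracts, L) in enumerate(
            zip(self.tracts, gmap.chrom_lengths_bp)
        ):
            pos = 0
            for tr in chrom_tracts:
                if tr.chrom != c or tr.start_bp != pos or tr.end_bp <= tr.start_bp:
                    raise GenomeMapError(f"gap/overlap on chromosome {c} at {pos}")
                if tr.source not in (1, 2):
                    raise GenomeMapError(f"bad source label {tr.source}")
                pos = tr.end_bp
            if pos != L:
                raise GenomeMapError(f"chromosome {c} tiling ends at {pos} != {L}")

    def source1_bp(self) -> int:
        return sum(
            tr.end_bp - tr.start_bp
            for chrom in self.tracts
            for tr in chrom
            if tr.source == 1
        )


def merge_tracts(hap: Haplotype) -> Haplotype:
    """Merge adjacent same-source tracts; idempotent, tiling preserved."""
    merged: list[list[Tract]] = []
    for chrom_tracts in hap.tracts:
        out: list[Tract] = []
        for tr in chrom_tracts:
            if out and out[-1].source == tr.source and out[-1].end_bp == tr.start_bp:
                out[-1] = Tract(tr.chrom, out[-1].start_bp, tr.end_bp, tr.source)
            else:
                out.append(tr)
        merged.append(out)
    return Haplotype(merged)


@dataclass
class Individual:
    """A diploid individual with social group and cached global ancestry.

    ``x`` is the fraction of the diploid genome derived from source
    population 1; unadmixed founders have x in {0, 1}.
    """

    hap1: Haplotype
    hap2: Haplotype
    social_group: str = "A"  # 'A' or 'B'
    x: float = 0.0
    is_migrant: bool = False

    @classmethod
    def founder(
        cls, source: int, gmap: GenomeMap, social_group: str | None = None
    ) -> "Individual":
        group = social_group if social_group is not None else ("A" if source == 1 else "B")
        ind = cls(
            Haplotype.unadmixed(source, gmap),
            Haplotype.unadmixed(source, gmap),
            social_group=group,
            is_migrant=True,
        )
        ind.x = 1.0 if source == 1 else 0.0
        return ind


def global_ancestry(ind: Individual, gmap: GenomeMap) -> float:
    """Source-1 bp summed over both haplotypes divided by 2L."""
    ind.hap1.validate(gmap)
    ind.hap2.validate(gmap)
    total = ind.hap1.source1_bp() + ind.hap2.source1_bp()
    return total / (2 * gmap.total_length_bp)


def _draw_crossovers(length_bp: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson number of crossovers, uniform, floored to bp; pairs at the
    same bp cancel."""
    k = rng.poisson(length_bp * rate)
    pos = np.floor(rng.random(k) * length_bp).astype(np.int64)
    if pos.size == 0:
        return pos
    uniq, counts = np.unique(pos, return_counts=True)
    return uniq[counts % 2 == 1]


def _meiose_chromosome(
    tracts1: Sequence[Tract],
    tracts2: Sequence[Tract],
    xovers: Iterable[int],
    start_hap: int,
    length_bp: int,
) -> list[Tract]:
    """Reference single-chromosome meiosis: copy segments alternating
    between the two parental haplotypes at the given crossover positions,
    starting from ``start_hap`` (0 or 1), merging same-source neighbours.
    """
    raw = [int(v) for v in xovers]
    # crossovers at the same bp cancel pairwise
    xo = sorted(v for v in set(raw) if raw.count(v) % 2 == 1)
    bounds = [0] + [v for v in xo if 0 < v < length_bp] + [length_bp]
    # a crossover at position 0 simply flips the starting template
    flips = sum(1 for v in xo if v == 0)
    cur = (start_hap + flips) % 2
    haps = (tracts1, tracts2)
    chrom = tracts1[0].chrom if tracts1 else 0
    out: list[Tract] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo == hi:
            continue
        for tr in haps[cur]:
            s = max(tr.start_bp, lo)
            e = min(tr.end_bp, hi)
            if s < e:
                if out and out[-1].source == tr.source and out[-1].end_bp == s:
                    out[-1] = Tract(chrom, out[-1].start_bp, e, tr.source)
                else:
                    out.append(Tract(chrom, s, e, tr.source))
        cur = 1 - cur
    return out


def sample_gamete(
    parent: Individual, gmap: GenomeMap, rng: np.random.Generator
) -> Haplotype:
    """Reference meiosis: one recombinant haplotype from ``parent``.

    Per chromosome, the crossover count is Poisson(chrom_length * rate),
    positions uniform, the starting haplotype is chosen with probability
    1/2 and chromosomes assort independently.
    """
    chroms: list[list[Tract]] = []
    for c, L in enumerate(gmap.chrom_lengths_bp):
        xo = _draw_crossovers(L, gmap.recomb_rate, rng)
        start = int(rng.integers(0, 2))
        chroms.append(
            _meiose_chromosome(parent.hap1.tracts[c], parent.hap2.tracts[c], xo, start, L)
        )
    return Haplotype(chroms)


# ---------------------------------------------------------------------------
# Vectorised population layer
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeSwitches:
    """Ancestry switch points for all haplotype rows on one chromosome.

    Row ``2*i`` is haplotype 1 of individual ``i``, row ``2*i + 1``
    haplotype 2.  ``pos[indptr[r]:indptr[r+1]]`` are the sorted switch
    positions (strictly inside ``(0, length_bp)``) of row ``r`` and
    ``source1_at_0[r]`` says whether the row starts on source 1.  Sources
    alternate across switch points.
    """

    length_bp: int
    pos: np.ndarray  # int64, concatenated sorted switch positions
    indptr: np.ndarray  # int64, len n_rows + 1
    source1_at_0: np.ndarray  # bool, len n_rows

    @property
    def n_rows(self) -> int:
        return len(self.source1_at_0)

    def counts(self) -> np.ndarray:
        return np.diff(self.indptr)

    def row_keys(self) -> np.ndarray:
        """Globally sorted keys row * (L+1) + pos for vectorised searches."""
        stride = self.length_bp + 1
        rows = np.repeat(np.arange(self.n_rows, dtype=np.int64), self.counts())
        return rows * stride + self.pos

    def source1_bp_per_row(self) -> np.ndarray:
        """Source-1 bp per haplotype row (alternating-interval sum)."""
        L = self.length_bp
        k = self.counts()
        j = np.arange(len(self.pos), dtype=np.int64) - np.repeat(self.indptr[:-1], k)
        signed = np.where(j % 2 == 0, self.pos, -self.pos)
        rows = np.repeat(np.arange(self.n_rows, dtype=np.int64), k)
        # length of intervals whose source equals source-at-0
        e = np.bincount(rows, weights=signed, minlength=self.n_rows)
        e = e + np.where(k % 2 == 0, L, 0)
        out = np.where(self.source1_at_0, e, L - e)
        return out.astype(np.int64)

    def tract_lengths(self) -> np.ndarray:
        """All tract lengths (bp) pooled across rows."""
        k = self.counts()
        L = self.length_bp
        pieces = []
        if len(self.pos):
            within = np.diff(self.pos)
            # mask out diffs that straddle row boundaries
            boundary = np.zeros(len(self.pos), dtype=bool)
            interior = self.indptr[1:-1]
            boundary[interior[interior < len(self.pos)]] = True
            pieces.append(within[~boundary[1:]])
            has = k > 0
            first = self.pos[self.indptr[:-1][has]]
            last = L - self.pos[self.indptr[1:][has] - 1]
            pieces.extend([first, last])
        empty = k == 0
        if empty.any():
            pieces.append(np.full(int(empty.sum()), L, dtype=np.int64))
        return np.concatenate(pieces) if pieces else np.empty(0, dtype=np.int64)

    def tract_lengths_by_source(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths_bp, source_labels) for all tracts pooled across rows."""
        k = self.counts()
        L = self.length_bp
        lengths = []
        sources = []
        for r in range(self.n_rows):
            p = self.pos[self.indptr[r] : self.indptr[r + 1]]
            bounds = np.concatenate([[0], p, [L]])
            lens = np.diff(bounds)
            s0 = 1 if self.source1_at_0[r] else 2
            src = np.where(np.arange(len(lens)) % 2 == 0, s0, 3 - s0)
            lengths.append(lens)
            sources.append(src)
        return np.concatenate(lengths), np.concatenate(sources)


@dataclass
class PopulationGenomes:
    """Flat tract representation for a whole population."""

    gmap: GenomeMap
    chroms: list[ChromosomeSwitches]

    @property
    def n_individuals(self) -> int:
        return self.chroms[0].n_rows // 2

    @classmethod
    def from_founder_sources(
        cls, sources: np.ndarray, gmap: GenomeMap
    ) -> "PopulationGenomes":
        """Unadmixed individuals; ``sources`` has one label (1 or 2) per
        individual, applied to both haplotypes."""
        sources = np.asarray(sources)
        s0 = np.repeat(sources == 1, 2)
        chroms = [
            ChromosomeSwitches(
                L,
                np.empty(0, dtype=np.int64),
                np.zeros(2 * len(sources) + 1, dtype=np.int64),
                s0.copy(),
            )
            for L in gmap.chrom_lengths_bp
        ]
        return cls(gmap, chroms)

    def global_ancestry(self) -> np.ndarray:
        """x per individual: source-1 bp over both haplotypes / 2L."""
        n = self.n_individuals
        total = np.zeros(n, dtype=np.int64)
        for ch in self.chroms:
            per_row = ch.source1_bp_per_row()
            total += per_row[0::2] + per_row[1::2]
        return total / (2.0 * self.gmap.total_length_bp)

    def tract_lengths_bp(self) -> np.ndarray:
        return np.concatenate([ch.tract_lengths() for ch in self.chroms])

    def tract_counts_per_individual(self) -> np.ndarray:
        n = self.n_individuals
        out = np.zeros(n, dtype=np.int64)
        for ch in self.chroms:
            per_row = ch.counts() + 1
            out += per_row[0::2] + per_row[1::2]
        return out

    def validate(self) -> None:
        """Structural invariants: sorted strictly-interior switch points and
        exact per-individual coverage (sum of tract lengths == 2L)."""
        for ch in self.chroms:
            k = ch.counts()
            if (k < 0).any() or ch.indptr[0] != 0 or ch.indptr[-1] != len(ch.pos):
                raise GenomeMapError("corrupt CSR index")
            if len(ch.pos):
                if ch.pos.min() <= 0 or ch.pos.max() >= ch.length_bp:
                    raise GenomeMapError("switch point outside (0, L)")
                rows = np.repeat(np.arange(ch.n_rows), k)
                order_ok = np.all(
                    (np.diff(ch.pos) > 0) | (np.diff(rows) != 0)
                )
                if not order_ok:
                    raise GenomeMapError("switch points not strictly increasing")

    def subset(self, idx: np.ndarray) -> "PopulationGenomes":
        """Genomes of the individuals in ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=np.int64)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        chroms = []
        for ch in self.chroms:
            k = ch.counts()[rows]
            gather = _ragged_gather_indices(ch.indptr, rows)
            new_indptr = np.concatenate([[0], np.cumsum(k)])
            chroms.append(
                ChromosomeSwitches(
                    ch.length_bp,
                    ch.pos[gather],
                    new_indptr.astype(np.int64),
                    ch.source1_at_0[rows].copy(),
                )
            )
        return PopulationGenomes(self.gmap, chroms)


def _ragged_gather_indices(indptr: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Flat indices selecting, in order, the CSR segments of ``rows``."""
    starts = indptr[rows]
    counts = indptr[rows + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return np.repeat(starts - offsets, counts) + np.arange(total, dtype=np.int64)


def _gametes_from_crossovers(
    ch: ChromosomeSwitches,
    row_a: np.ndarray,
    row_b: np.ndarray,
    xo_pos: np.ndarray,
    xo_gid: np.ndarray,
    n_gametes: int,
) -> ChromosomeSwitches:
    """Deterministic core of vectorised meiosis for one chromosome.

    ``row_a``/``row_b`` give, per gamete, the starting and alternate
    parental haplotype rows.  ``xo_pos`` are parity-deduplicated crossover
    positions in ``[1, L)`` (sorted within gamete), ``xo_gid`` the gamete id
    of each crossover.
    """
    L = ch.length_bp
    stride = L + 1
    xo_keys = xo_gid * stride + xo_pos
    xo_counts = np.bincount(xo_gid, minlength=n_gametes)
    xo_indptr = np.concatenate([[0], np.cumsum(xo_counts)]).astype(np.int64)
    parent_keys = ch.row_keys()

    kept_keys = []

    # template switches that survive: active template on both sides, no
    # crossover exactly at the switch
    for template, rows in (("A", row_a), ("B", row_b)):
        counts = ch.indptr[rows + 1] - ch.indptr[rows]
        gather = _ragged_gather_indices(ch.indptr, rows)
        p = ch.pos[gather]
        gid = np.repeat(np.arange(n_gametes, dtype=np.int64), counts)
        keys = gid * stride + p
        c_left = np.searchsorted(xo_keys, keys, side="left") - xo_indptr[gid]
        c_right = np.searchsorted(xo_keys, keys, side="right") - xo_indptr[gid]
        parity_active = (c_left % 2 == 0) if template == "A" else (c_left % 2 == 1)
        keep = parity_active & (c_left == c_right)
        kept_keys.append(keys[keep])

    # crossover junctions where the source actually changes
    if len(xo_pos):
        j = np.arange(len(xo_pos), dtype=np.int64) - xo_indptr[:-1].repeat(xo_counts)
        from_a = j % 2 == 0
        r_old = np.where(from_a, row_a[xo_gid], row_b[xo_gid])
        r_new = np.where(from_a, row_b[xo_gid], row_a[xo_gid])
        key_old = r_old * stride + xo_pos
        key_new = r_new * stride + xo_pos
        cnt_old = np.searchsorted(parent_keys, key_old, side="left") - ch.indptr[r_old]
        cnt_new = np.searchsorted(parent_keys, key_new, side="right") - ch.indptr[r_new]
        src_old = ch.source1_at_0[r_old] ^ (cnt_old % 2 == 1)
        src_new = ch.source1_at_0[r_new] ^ (cnt_new % 2 == 1)
        kept_keys.append((xo_gid * stride + xo_pos)[src_old != src_new])

    all_keys = np.concatenate(kept_keys) if kept_keys else np.empty(0, dtype=np.int64)
    all_keys.sort(kind="stable")
    out_gid = all_keys // stride
    out_pos = all_keys % stride
    out_counts = np.bincount(out_gid, minlength=n_gametes)
    out_indptr = np.concatenate([[0], np.cumsum(out_counts)]).astype(np.int64)
    return ChromosomeSwitches(
        L, out_pos.astype(np.int64), out_indptr, ch.source1_at_0[row_a].copy()
    )


def sample_gametes(
    genomes: PopulationGenomes,
    parent_idx: np.ndarray,
    rng: np.random.Generator,
) -> list[ChromosomeSwitches]:
    """One recombinant gamete per entry of ``parent_idx``, all chromosomes.

    Returns one ChromosomeSwitches per chromosome with ``len(parent_idx)``
    rows (one haplotype per gamete).
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    G = len(parent_idx)
    rate = genomes.gmap.recomb_rate
    out = []
    for ch in genomes.chroms:
        L = ch.length_bp
        k = rng.poisson(L * rate, size=G)
        total = int(k.sum())
        gid = np.repeat(np.arange(G, dtype=np.int64), k)
        raw = np.floor(rng.random(total) * L).astype(np.int64)
        start = rng.integers(0, 2, size=G)

        stride = L + 1
        keys = gid * stride + raw
        keys.sort(kind="stable")
        uniq, counts = np.unique(keys, return_counts=True)
        odd = uniq[counts % 2 == 1]
        xo_gid = odd // stride
        xo_pos = odd % stride
        # a crossover at position 0 flips the starting template
        at0 = xo_pos == 0
        if at0.any():
            flip = np.bincount(xo_gid[at0], minlength=G)
            start = (start + flip) % 2
            xo_gid, xo_pos = xo_gid[~at0], xo_pos[~at0]

        row_a = 2 * parent_idx + start
        row_b = 2 * parent_idx + (1 - start)
        out.append(_gametes_from_crossovers(ch, row_a, row_b, xo_pos, xo_gid, G))
    return out


def combine_gametes(
    gmap: GenomeMap,
    gametes1: list[ChromosomeSwitches],
    gametes2: list[ChromosomeSwitches],
) -> PopulationGenomes:
    """Diploid genomes with hap1 from ``gametes1`` and hap2 from
    ``gametes2`` (row i of each becomes individual i)."""
    chroms = []
    for g1, g2 in zip(gametes1, gametes2):
        n = g1.n_rows
        c1 = g1.counts()
        c2 = g2.counts()
        counts = np.empty(2 * n, dtype=np.int64)
        counts[0::2] = c1
        counts[1::2] = c2
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        pos = np.empty(len(g1.pos) + len(g2.pos), dtype=np.int64)
        idx1 = _ragged_gather_indices(g1.indptr, np.arange(n, dtype=np.int64))
        idx2 = _ragged_gather_indices(g2.indptr, np.arange(n, dtype=np.int64))
        # scatter rows into interleaved layout
        dest1 = _ragged_gather_indices(indptr, 2 * np.arange(n, dtype=np.int64))
        dest2 = _ragged_gather_indices(indptr, 2 * np.arange(n, dtype=np.int64) + 1)
        pos[dest1] = g1.pos[idx1]
        pos[dest2] = g2.pos[idx2]
        s0 = np.empty(2 * n, dtype=bool)
        s0[0::2] = g1.source1_at_0
        s0[1::2] = g2.source1_at_0
        chroms.append(ChromosomeSwitches(g1.length_bp, pos, indptr, s0))
    return PopulationGenomes(gmap, chroms)


def haplotype_from_switches(
    ch: ChromosomeSwitches, row: int, chrom: int
) -> list[Tract]:
    """Tract list for one haplotype row of one chromosome (for export and
    for round-tripping against the object layer)."""
    p = ch.pos[ch.indptr[row] : ch.indptr[row + 1]]
    bounds = np.concatenate([[0], p, [ch.length_bp]])
    s0 = 1 if ch.source1_at_0[row] else 2
    return [
        Tract(chrom, int(bounds[i]), int(bounds[i + 1]), s0 if i % 2 == 0 else 3 - s0)
        for i in range(len(bounds) - 1)
    ]


def individual_from_population(
    genomes: PopulationGenomes, i: int
) -> tuple[Haplotype, Haplotype]:
    """Object-layer haplotypes of individual ``i``."""
    hap1 = Haplotype(
        [haplotype_from_switches(ch, 2 * i, c) for c, ch in enumerate(genomes.chroms)]
    )
    hap2 = Haplotype(
        [haplotype_from_switches(ch, 2 * i + 1, c) for c, ch in enumerate(genomes.chroms)]
    )
    return hap1, hap2
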