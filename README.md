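# assortmate

Forward-in-time, individual-based simulation of **ancestry-assortative
mating** in a recently admixed population, with the analysis stack needed to
ask whether different mate-choice *mechanisms* can be distinguished from the
mating *outcomes* they produce — and what they do to downstream inference
such as tract-length admixture dating.

## What it does

* **Genomes as local-ancestry tracts.** Each individual carries two
  haplotypes over 22 independently segregating chromosomes (human-autosome
  shaped, 2.88 Gb total, uniform recombination 1e-8 Morgan/bp, so
  1 cM = 1 Mb). Meiosis draws Poisson crossover counts per chromosome with
  uniform positions and no interference. An individual's global ancestry
  proportion `x` is the fraction of its diploid genome from source
  population 1.
* **Four mate-choice models on a common bias parameter α.** Each generation
  consists of N mating events: parent 1 is drawn uniformly, parent 2 with
  probability proportional to a mating weight ψ (selfing prohibited):
  * `stationary` — ψ = exp(−c·|Δx|), c = ln α;
  * `increasing` — ψ = exp(−(c/σ²ₓ(t))·|Δx|), c = ln α · σ²ₓ(0): choosiness
    grows as the population homogenises;
  * `broad` — ψ is a Gaussian density in Δx with σ² = 1/(2 ln α);
  * `social_group` — same-group weight 1 − 1/(α+1), cross-group 1/(α+1),
    with a binary non-genetic group label inherited from parent 1;
  * `random` (or α = 1) — uniform.

  All four are calibrated so that at first contact an individual is α times
  more likely to pick a mate from its own source population, giving the same
  first-generation mate correlation r = (α−1)/(α+1).
* **Scenarios.** Single admixture pulse (founding proportion m, default
  0.5), or continuous migration replacing a fixed fraction of each
  generation with unadmixed migrants.
* **Summaries.** Mate-pair Pearson correlation r(xᵢ, xⱼ) with a one-sided
  permutation test, ancestry variance σ²ₓ(t), |Δx| distributions, hexagonal-
  bin mating densities with a connected-cluster count, a bimodality check
  (Hartigan's dip test with a Gaussian-mixture BIC cross-check), and
  migrant-mating prevalence.
* **Tract-based admixture dating.** Exponential MLE on tract lengths
  (λ̂ = 1/mean in Morgans) inverted through λ = (t+1)·m; assortative mating
  preserves long tracts and biases t̂ toward too-recent admixture.

## Quick start

```python
from assortmate import SimConfig, run_simulation, fit_timing

cfg = SimConfig(model="increasing", alpha=5, N=1000, generations=20,
                seed=1, record_tracts_at=(20,))
res = run_simulation(cfg)
print(res.summaries[["t", "r_mates", "sigma2_x"]].tail())
print(fit_timing(res.tract_samples[20], m=0.5).t_hat)  # biased downward
```

Command line:

```sh
# one run, all tables
assortmate simulate --model stationary --alpha 10 -N 1000 -T 20 \
    --seed 1 --record-tracts-at 20 --out runs/stat10

# canned multi-run analyses (alpha grid x replicates)
assortmate experiment --recipe correlation -N 1000 -T 20 --out runs/corr
assortmate experiment --recipe timing -N 1000 -T 50 --out runs/timing

# date admixture from a tract table (length_cm column or BED-like export)
assortmate infer-timing --tracts runs/stat10/tract_lengths_t20.tsv --m 0.5
```

All outputs are text (TSV/YAML/JSON). Runs are deterministic given
`(seed, replicate)`: the same configuration reproduces byte-identical
tables.

## Layout

| Module | Contents |
| --- | --- |
| `assortmate.genome` | genome map, tract bookkeeping, vectorised meiosis (with a small object-layer reference implementation) |
| `assortmate.mate_choice` | the four ψ functions and their α calibration |
| `assortmate.engine` | generation loop, migration, per-generation records |
| `assortmate.summaries` | r, permutation test, σ²ₓ, Δx, hexbin clusters, dip test |
| `assortmate.tract_inference` | exponential fit and admixture-time inversion |
| `assortmate.fixtures` | seeded synthetic inputs for testing the analyses |
| `assortmate.cli` / `assortmate.io` | command line, TSV/BED/YAML/JSON writers |

`docs/methods.md` states the model conventions precisely;
`scripts/acceptance.py --seed <int> --out <path>` recomputes the headline
quantitative results from scratch.

## Testing

```sh
python -m pytest -q
```

The suite checks the vectorised meiosis exactly against the reference
implementation, the dip statistic against an independent linear-programming
oracle, analytic calibration identities, and the headline acceptance
criteria (some of which run multi-minute simulation batches).

A few acceptance tests encode fixed quantitative target ranges that the
implementation is known not to meet at the tested scales and seeds, and are
deliberately left failing rather than loosened: the mean timing-bias range
(the increasing-preference model, as calibrated here, preserves far more
long-tract signal than the target assumed), the upper bound on the
stationary α=10 correlation (a 5-replicate maximum with substantial
by-chance mass above the bound), the social α=4 permutation cell (a power
artifact of the N=2,000 test scale; significant at N=10,000), and the
hexbin matched-pair cluster counts. The comments in
`tests/test_acceptance.py` record the quantitative details.
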