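"""Coalescent simulation of multi-population phased haplotype samples.

The neutral model is a three-population human-like history: an ancestral
African population, an out-of-Africa split 3,500 generations ago through a
bottlenecked founder population, and a European/Asian split 2,000
generations ago with growth in both daughter populations.  Only the two
split times (and, for sweeps, the selection parameters) are treated as
fixed constants of the study design; the remaining demographic sizes are
exposed in the configuration with documented defaults in the style of the
calibrated human demographic models.

The sweep scenario conditions a focal allele to rise under genic selection
(default s = 0.015) to a final sample frequency of 0.99 at the time of
sampling.  The structured-coalescent sweep model of the underlying engine
(msprime) supports a single panmictic deme only, so sweep simulations — and
their matched neutral controls — run with ``collapse_populations`` set: one
deme whose size defaults to a present-day-scale effective size (1e5), with
population labels assigned in equal blocks.  The scenario-comparison
experiments pool all haplotypes into a global population, so this is the
natural surface for them.

After simulation, sites are filtered with the minor-allele-frequency rule
used for simulated data: a site is removed only when its MAF is below the
threshold in *every* population (mode ``any_population``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .haplotype_io import FilterStats, HaplotypeMatrix, SiteRecord, maf_filter

__all__ = [
    "SweepParams",
    "SimulationConfig",
    "build_demography",
    "simulate_neutral",
    "simulate_sweep",
    "subsample_haplotypes",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SweepParams:
    """Selective-sweep conditioning parameters."""

    selection_coefficient: float = 0.015
    final_frequency: float = 0.99
    position: int | None = None  # defaults to the region midpoint
    dt: float = 1e-6
    max_retries: int = 10

    def __post_init__(self):
        if not (0 < self.final_frequency <= 1):
            raise ValueError("final_frequency must be in (0, 1]")
        if self.selection_coefficient < 0:
            raise ValueError("selection_coefficient must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Demography, sweep, sample-size and seed parameters.

    Sizes are diploid effective sizes.  ``n_haplotypes_per_pop`` must be
    even (two haplotypes per simulated diploid individual).
    """

    n_haplotypes_per_pop: int = 5000
    populations: tuple[str, ...] = ("AFR", "EUR", "ASN")
    ooa_split_generations: float = 3500.0
    eurasian_split_generations: float = 2000.0
    region_length_bp: int = 50_000
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    ancestral_size: float = 12_500.0
    african_size: float = 12_500.0
    ooa_bottleneck_size: float = 1_800.0
    eurasian_founder_size: float = 1_000.0
    eurasian_present_size: float = 10_000.0
    collapse_populations: bool = False
    panmictic_size: float = 100_000.0
    maf_threshold: float = 0.01
    apply_maf: bool = True
    sweep: SweepParams | None = None
    seed: int = 1
    chromosome: str = "sim1"

    def __post_init__(self):
        if self.n_haplotypes_per_pop <= 0:
            raise ValueError("n_haplotypes_per_pop must be positive")
        if self.n_haplotypes_per_pop % 2:
            raise ValueError("n_haplotypes_per_pop must be even (diploid samples)")
        if len(self.populations) != 3:
            raise ValueError("exactly three population labels are expected")


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % _SEED_MOD + 1 for s in ss.generate_state(n)]


def build_demography(config: SimulationConfig):
    """The three-population split demography as an msprime Demography."""
    import msprime

    afr, eur, asn = config.populations
    growth = (
        np.log(config.eurasian_present_size / config.eurasian_founder_size)
        / config.eurasian_split_generations
    )
    dem = msprime.Demography()
    dem.add_population(name=afr, initial_size=config.african_size)
    dem.add_population(
        name=eur, initial_size=config.eurasian_present_size, growth_rate=growth
    )
    dem.add_population(
        name=asn, initial_size=config.eurasian_present_size, growth_rate=growth
    )
    dem.add_population(name="OOA", initial_size=config.ooa_bottleneck_size)
    dem.add_population(name="ANC", initial_size=config.ancestral_size)
    dem.add_population_split(
        time=config.eurasian_split_generations, derived=[eur, asn], ancestral="OOA"
    )
    dem.add_population_split(
        time=config.ooa_split_generations, derived=[afr, "OOA"], ancestral="ANC"
    )
    return dem


def _matrix_from_ts(ts, config: SimulationConfig) -> HaplotypeMatrix:
    genotypes = ts.genotype_matrix().T.astype(np.uint8)  # haplotypes x sites
    positions = ts.sites_position.astype(np.int64) + 1  # to 1-based
    # discrete-genome sites are unique, so +1 keeps strict ordering
    sites = [
        SiteRecord(chromosome=config.chromosome, position=int(p)) for p in positions
    ]
    labels = np.concatenate(
        [
            np.full(config.n_haplotypes_per_pop, pop, dtype=object)
            for pop in config.populations
        ]
    )
    return HaplotypeMatrix(sites=sites, alleles=genotypes, population_labels=labels)


def _finalize(matrix: HaplotypeMatrix, config: SimulationConfig) -> HaplotypeMatrix:
    stats = FilterStats()
    if config.apply_maf:
        matrix, dropped = maf_filter(matrix, config.maf_threshold, "any_population")
        stats.low_maf = dropped
    matrix.filter_stats = stats
    return matrix


def simulate_neutral(config: SimulationConfig) -> HaplotypeMatrix:
    """Sample phased haplotypes under the neutral demography.

    Deterministic given ``config.seed``.  With ``collapse_populations`` the
    three demes are replaced by one of size ``panmictic_size`` (labels
    still assigned in blocks) — the matched control for sweep runs.
    """
    import msprime

    if config.sweep is not None:
        raise ValueError("config.sweep must be None for simulate_neutral")
    anc_seed, mut_seed = _derive_seeds(config.seed, 2)
    n_ind = config.n_haplotypes_per_pop // 2
    if config.collapse_populations:
        ts = msprime.sim_ancestry(
            samples=3 * n_ind,
            population_size=config.panmictic_size,
            sequence_length=config.region_length_bp,
            recombination_rate=config.recombination_rate,
            random_seed=anc_seed,
        )
    else:
        dem = build_demography(config)
        ts = msprime.sim_ancestry(
            samples={pop: n_ind for pop in config.populations},
            demography=dem,
            sequence_length=config.region_length_bp,
            recombination_rate=config.recombination_rate,
            random_seed=anc_seed,
        )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        random_seed=mut_seed,
    )
    return _finalize(_matrix_from_ts(ts, config), config)


def _focal_column(ts, position: float, target_frequency: float) -> np.ndarray:
    """0/1 sample column for the node whose leaf fraction at ``position`` is
    closest to the target frequency — the conditioned selected allele."""
    tree = ts.at(position)
    n = ts.num_samples
    best, best_node = np.inf, None
    for u in tree.nodes():
        if tree.parent(u) == -1:
            continue
        gap = abs(tree.num_samples(u) / n - target_frequency)
        if gap < best:
            best, best_node = gap, u
    col = np.zeros(n, dtype=np.uint8)
    if best_node is not None:
        col[list(tree.samples(best_node))] = 1
    return col


def simulate_sweep(config: SimulationConfig) -> HaplotypeMatrix:
    """Sample haplotypes conditioned on a completed selective sweep.

    The sweep phase runs the structured-coalescent genic-selection model
    from the present back to the sweep's origin, then hands over to the
    standard coalescent.  Requires ``collapse_populations`` (single-deme
    sweep support in the engine); the focal selected allele is inserted at
    the sweep position and is exempt from the MAF filter.  A failed sweep
    trajectory is retried with fresh derived seeds up to ``max_retries``
    times.
    """
    import msprime

    if config.sweep is None:
        raise ValueError("config.sweep must be set for simulate_sweep")
    if not config.collapse_populations:
        raise ValueError(
            "sweep simulations require collapse_populations=True "
            "(single-deme sweep model); the matched neutral control is "
            "simulate_neutral with the same flag"
        )
    sweep = config.sweep
    position = (
        sweep.position if sweep.position is not None else config.region_length_bp // 2
    )
    n_ind = 3 * (config.n_haplotypes_per_pop // 2)
    model = [
        msprime.SweepGenicSelection(
            position=position,
            start_frequency=1.0 / (2 * config.panmictic_size),
            end_frequency=sweep.final_frequency,
            s=sweep.selection_coefficient,
            dt=sweep.dt,
        ),
        msprime.StandardCoalescent(),
    ]
    seeds = _derive_seeds(config.seed, 2 * (sweep.max_retries + 1))
    last_error: Exception | None = None
    for attempt in range(sweep.max_retries + 1):
        anc_seed, mut_seed = seeds[2 * attempt : 2 * attempt + 2]
        try:
            ts = msprime.sim_ancestry(
                samples=n_ind,
                population_size=config.panmictic_size,
                sequence_length=config.region_length_bp,
                recombination_rate=config.recombination_rate,
                model=model,
                random_seed=anc_seed,
            )
        except Exception as exc:  # unattainable trajectory; retry
            last_error = exc
            logger.warning("sweep attempt %d failed: %s", attempt + 1, exc)
            continue
        ts = msprime.sim_mutations(
            ts,
            rate=config.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=mut_seed,
        )
        matrix = _matrix_from_ts(ts, config)
        matrix = _finalize(matrix, config)
        focal = _focal_column(ts, position, sweep.final_frequency)
        matrix = _insert_focal_site(matrix, config, position, focal)
        return matrix
    raise RuntimeError(
        f"sweep trajectory failed after {sweep.max_retries + 1} attempts: {last_error}"
    )


def _insert_focal_site(
    matrix: HaplotypeMatrix,
    config: SimulationConfig,
    position: int,
    column: np.ndarray,
) -> HaplotypeMatrix:
    """Insert the selected-allele column at its map position, nudging it off
    any occupied coordinate."""
    pos = int(position)
    taken = {s.position for s in matrix.sites}
    while pos in taken:
        pos += 1
    site = SiteRecord(chromosome=config.chromosome, position=pos)
    positions = [s.position for s in matrix.sites]
    j = int(np.searchsorted(positions, pos))
    sites = matrix.sites[:j] + [site] + matrix.sites[j:]
    alleles = np.insert(matrix.alleles, j, column, axis=1)
    out = HaplotypeMatrix(
        sites=sites, alleles=alleles, population_labels=matrix.population_labels
    )
    out.filter_stats = matrix.filter_stats
    return out


def subsample_haplotypes(
    matrix: HaplotypeMatrix,
    n: int,
    seed: int | None = None,
    stratified: bool = True,
    nested: bool = False,
) -> HaplotypeMatrix:
    """Random haplotype rows without replacement, seeded.

    ``n`` is per population when ``stratified`` (the default), else a pooled
    total.  In ``nested`` mode a fixed seed-derived permutation is truncated,
    so for the same seed sample(m) is a subset of sample(n) whenever m <= n.
    """
    rng = np.random.default_rng(seed)
    if stratified:
        chosen: list[np.ndarray] = []
        for pop in matrix.populations():
            rows = matrix.rows_for_population(pop)
            if n > len(rows):
                raise ValueError(
                    f"cannot sample {n} haplotypes from the {len(rows)} of {pop}"
                )
            perm = rng.permutation(rows)
            chosen.append(np.sort(perm[:n]))
        idx = np.concatenate(chosen)
    else:
        if n > matrix.n_haplotypes:
            raise ValueError(
                f"cannot sample {n} haplotypes from {matrix.n_haplotypes}"
            )
        perm = rng.permutation(matrix.n_haplotypes)
        idx = np.sort(perm[:n])
    # nested mode is implicit: the permutation depends only on the seed, and
    # truncation of a fixed permutation is monotone in n.  The flag is kept
    # for interface clarity.
    del nested
    return matrix.subset_rows(idx)
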