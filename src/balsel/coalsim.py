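"""Neutral coalescent simulation, mutation-rate calibration and
simulation-based p-values.

The simulator is a standard backwards-in-time coalescent with
recombination (ancestral recombination graph), piecewise-constant
population sizes, splits and migration, with infinite-sites mutations on a
continuous interval mapped to discrete bp for output. Simulation is
delegated to msprime behind this module's interface; every run is
deterministic given its seed.

Demographic presets ("CEU-like", "YRI-like", "EAS-like") are deliberately
coarse piecewise-constant approximations of an out-of-Africa history with
bottlenecks — adequate for generating realistic null distributions, not
reproductions of any fitted model. The parameter tables are in
docs/methods.md.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import msprime
import numpy as np
import pandas as pd

from balsel.diversity import diversity_summary
from balsel.neutrality import all_statistics
from balsel.regionio import HaplotypeAlignment, Region

logger = logging.getLogger(__name__)

Tail = Literal["upper", "lower", "two_sided"]


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant population history with optional splits/migration.

    ``epochs`` maps each population to ``[(start_generation, size), ...]``
    ordered by increasing start time (first entry must start at 0);
    ``splits`` lists ``(time, derived, ancestral)`` population merges
    backwards in time; ``migration`` maps ordered pairs to per-generation
    rates.
    """

    name: str
    epochs: dict[str, list[tuple[float, float]]]
    splits: list[tuple[float, str, str]] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, eps in self.epochs.items():
            if not eps or eps[0][0] != 0:
                raise ValueError(f"{pop}: first epoch must start at time 0")
            times = [t for t, _ in eps]
            if sorted(times) != times or any(t < 0 for t in times):
                raise ValueError(f"{pop}: epoch times must be ordered, >= 0")
            if any(size <= 0 for _, size in eps):
                raise ValueError(f"{pop}: population sizes must be positive")
        if any(rate < 0 for rate in self.migration.values()):
            raise ValueError("migration rates must be non-negative")

    @property
    def populations(self) -> list[str]:
        return list(self.epochs)

    def present_size(self, population: str) -> float:
        return self.epochs[population][0][1]

    def to_msprime(self) -> msprime.Demography:
        # sizes are diploid N_e; simulations run with ploidy=1, where the
        # pairwise coalescence rate is 1/size, so sizes are doubled to keep
        # the diploid 1/(2N) rate and the generation time scale
        demography = msprime.Demography()
        for pop, eps in self.epochs.items():
            demography.add_population(name=pop, initial_size=2 * eps[0][1])
            for start, size in eps[1:]:
                demography.add_population_parameters_change(
                    time=start, population=pop, initial_size=2 * size)
        for (src, dst), rate in self.migration.items():
            demography.set_migration_rate(source=src, dest=dst, rate=rate)
        for time, derived, ancestral in sorted(self.splits):
            demography.add_population_split(
                time=time, derived=[derived], ancestral=ancestral)
        demography.sort_events()
        return demography


def demographic_preset(name: str) -> DemographicModel:
    """Packaged single-population presets: constant-size, and coarse
    bottleneck approximations for the three continental panels."""
    presets = {
        "constant": DemographicModel("constant", {"pop": [(0, 10_000)]}),
        "YRI-like": DemographicModel(
            "YRI-like", {"YRI": [(0, 12_500), (8_000, 7_000)]}),
        "CEU-like": DemographicModel(
            "CEU-like", {"CEU": [(0, 10_000), (2_000, 1_500),
                                 (2_120, 7_000)]}),
        "EAS-like": DemographicModel(
            "EAS-like", {"EAS": [(0, 10_000), (2_000, 1_000),
                                 (2_120, 7_000)]}),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    return presets[name]


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters for one region.

    Exactly one of ``theta`` (region total 4 N mu L, N = present size of the
    sampled population) or ``mu`` (per site per generation) must be given.
    ``rho`` is the region-total 4 N r L.
    """

    n: int
    L: int
    reps: int
    seed: int
    theta: float | None = None
    mu: float | None = None
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if (self.theta is None) == (self.mu is None):
            raise ValueError("give exactly one of theta or mu")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.mu is not None and self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    def rates(self, present_size: float) -> tuple[float, float]:
        """(mutation, recombination) per-site per-generation rates."""
        denom = 4.0 * present_size * self.L
        mu = self.mu if self.mu is not None else self.theta / denom
        return mu, self.rho / denom


@dataclass
class SimulationResult:
    """Per-replicate summary statistics plus recorded true TMRCAs.

    ``stats`` columns: S, theta_w, pi (per site), pi_total, D_T, Dstar,
    Fstar, tmrca_gen (generations). ``sfs`` holds the unfolded
    (derived-allele-count) spectrum summed over replicates.
    """

    params: SimParams
    model: DemographicModel
    seed: int
    stats: pd.DataFrame
    sfs: np.ndarray
    alignments: list[HaplotypeAlignment] | None = None
    tree_sequences: list | None = None


def calibrate_mu(d_per_site: float, split_time_years: float,
                 generation_years: float = 25.0) -> float:
    """Per-site per-generation mutation rate from outgroup divergence.

    Divergence accrues on both lineages since the species split, so
    mu = d / (2 * split_time_years / generation_years).
    """
    if split_time_years <= 0 or generation_years <= 0:
        raise ValueError("split time and generation time must be positive")
    if d_per_site < 0 or d_per_site >= 1:
        raise ValueError(f"divergence must be in [0, 1), got {d_per_site}")
    if d_per_site == 0:
        warnings.warn("zero divergence gives mu = 0 (degenerate calibration)",
                      stacklevel=2)
        return 0.0
    return d_per_site / (2.0 * split_time_years / generation_years)


def alignment_from_tree_sequence(ts, region: Region | None = None,
                                 population: str = "pop") -> HaplotypeAlignment:
    """Convert an infinite-sites tree sequence into a haplotype alignment.

    Continuous site positions are floored to bp and bumped to keep them
    strictly increasing; derived alleles are coded 1.
    """
    L = int(ts.sequence_length)
    if region is None:
        region = Region("sim", 0, L, "sim")
    geno = ts.genotype_matrix()  # sites x samples
    raw_pos = [site.position for site in ts.sites()]
    positions, prev = [], -1
    for p in raw_pos:
        ip = max(int(p), prev + 1)
        positions.append(ip)
        prev = ip
    if positions and positions[-1] >= region.end:
        raise ValueError("site density too high to map to discrete bp")
    n = ts.num_samples
    return HaplotypeAlignment(
        region=region,
        haplotypes=geno.T.astype(np.int8),
        positions=np.array(positions, dtype=np.int64),
        populations=np.array([population] * n, dtype=object),
        alleles=["AC"] * len(positions),  # 0 = ancestral A, 1 = derived C
    )


def _tmrca_generations(ts) -> float:
    """Max root time over marginal trees (= region TMRCA in generations)."""
    return max(tree.time(tree.root) for tree in ts.trees()
               if tree.num_roots == 1)


def simulate_neutral(
    params: SimParams,
    model: DemographicModel | str = "constant",
    sample_population: str | None = None,
    keep_alignments: bool = False,
    keep_tree_sequences: bool = False,
) -> SimulationResult:
    """Simulate ``params.reps`` neutral replicates and summarise each.

    Per-replicate statistics are computed through the same diversity and
    neutrality code used on observed data, so simulated null distributions
    are directly comparable.
    """
    if isinstance(model, str):
        model = demographic_preset(model)
    pop = sample_population or model.populations[0]
    mu, r = params.rates(model.present_size(pop))
    rng = np.random.default_rng(params.seed)
    seeds = rng.integers(1, 2**31 - 1, size=(params.reps, 2))

    region = Region("sim", 0, params.L, "sim")
    rows, sfs = [], np.zeros(params.n + 1, dtype=np.int64)
    alns = [] if keep_alignments else None
    tss = [] if keep_tree_sequences else None
    demography = model.to_msprime()
    for i in range(params.reps):
        ts = msprime.sim_ancestry(
            samples={pop: params.n}, ploidy=1, demography=demography,
            sequence_length=params.L, recombination_rate=r,
            discrete_genome=False, random_seed=int(seeds[i, 0]))
        ts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=int(seeds[i, 1]))
        aln = alignment_from_tree_sequence(ts, region, pop)
        summ = diversity_summary(aln)
        stats = (all_statistics(aln) if summ.S > 0
                 else {"D_T": np.nan, "Dstar": np.nan, "Fstar": np.nan})
        if summ.S:
            derived = (aln.haplotypes == 1).sum(axis=0)
            sfs += np.bincount(derived, minlength=params.n + 1)
        rows.append({"S": summ.S, "theta_w": summ.theta_w, "pi": summ.pi,
                     "pi_total": summ.pi * summ.L,
                     "tmrca_gen": _tmrca_generations(ts), **stats})
        if keep_alignments:
            alns.append(aln)
        if keep_tree_sequences:
            tss.append(ts)
    return SimulationResult(params=params, model=model, seed=params.seed,
                            stats=pd.DataFrame(rows), sfs=sfs,
                            alignments=alns, tree_sequences=tss)


def simulation_pvalue(observed: float, sims: SimulationResult,
                      statistic: str, tail: Tail = "upper") -> float:
    """p = (r + 1) / (m + 1) over replicates with a defined statistic.

    ``r`` counts replicates at least as extreme as the observation in the
    requested tail; the +1 correction avoids p = 0. The upper tail is the
    balancing-selection direction for all SFS statistics here.
    """
    vals = sims.stats[statistic].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    m = vals.size
    if m < 0.5 * len(sims.stats):
        raise ValueError(
            f"{statistic} undefined in more than half of replicates "
            f"({m}/{len(sims.stats)} defined)")
    if m < 100:
        raise ValueError(f"need >= 100 defined replicates, got {m}")
    upper = (np.sum(vals >= observed) + 1) / (m + 1)
    lower = (np.sum(vals <= observed) + 1) / (m + 1)
    if tail == "upper":
        return float(upper)
    if tail == "lower":
        return float(lower)
    return float(min(1.0, 2.0 * min(upper, lower)))
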