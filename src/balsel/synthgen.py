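"""Synthetic-data generation for the full pipeline.

Every generator is a pure function of its parameters and seed, and writes
(or returns) data in the shapes the readers and estimators consume, so
generated regions are drop-in stand-ins for resequenced ones. The defaults
mirror a Sanger-resequencing survey of 2-9 kb gene regions in ~40
chromosomes per population, with 5 kb neutral reference-window panels and
"balanced" regions built structurally from two or three deep haplotype
clades.

Balanced regions are constructed by joining independently simulated
neutral clade genealogies at specified split times and dropping Poisson
mutations on the long joining branches — the inference machinery only sees
genealogy shape, so the structural construction gives exact ground truth
(recorded in the returned truth dict) without forward simulation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from balsel.coalsim import DemographicModel, SimParams, simulate_neutral
from balsel.regionio import (
    MISSING,
    HaplotypeAlignment,
    OutgroupAlignment,
    Region,
    attach_outgroup,
    write_haplotype_fasta,
)

DEFAULT_MU = 2.5e-8        # per site per generation, divergence-calibrated
DEFAULT_NE = 10_000        # diploid effective size
DEFAULT_GENERATION = 25.0  # years


@dataclass(frozen=True)
class BalancedRegionSpec:
    """Specification of a structurally balanced region.

    ``clade_frequencies`` maps population -> one frequency per clade
    (summing to 1); ``split_times_years`` has one entry for two clades
    (the root) and two for three clades (first the join of clades 0 and 1,
    then the root where clade 2 attaches).
    """

    n: dict[str, int] = field(default_factory=lambda: {"CEU": 40})
    L: int = 4000
    clade_count: int = 2
    split_times_years: tuple[float, ...] = (5e6,)
    clade_frequencies: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"CEU": (0.5, 0.5)})
    mu: float = DEFAULT_MU
    rho: float = 0.0
    N_e: float = DEFAULT_NE
    generation_years: float = DEFAULT_GENERATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clade_count not in (2, 3):
            raise ValueError("clade_count must be 2 or 3")
        if len(self.split_times_years) != self.clade_count - 1:
            raise ValueError("need clade_count - 1 split times")
        if any(t <= 0 for t in self.split_times_years):
            raise ValueError("split times must be positive")
        for pop, freqs in self.clade_frequencies.items():
            if len(freqs) != self.clade_count:
                raise ValueError(f"{pop}: need one frequency per clade")
            if not math.isclose(sum(freqs), 1.0, abs_tol=1e-9):
                raise ValueError(f"{pop}: clade frequencies must sum to 1")
            if any(not (0 <= f <= 1) for f in freqs):
                raise ValueError(f"{pop}: frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class ThinningSpec:
    """Singleton-undercalling model for low-coverage emulation."""

    p_drop_singleton: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_drop_singleton <= 1.0):
            raise ValueError("p_drop_singleton must be in [0, 1]")


def _constant_model(N_e: float) -> DemographicModel:
    return DemographicModel("constant", {"pop": [(0, float(N_e))]})


def generate_neutral_region(
    n: int,
    L: int,
    theta: float | None = None,
    mu: float | None = None,
    rho: float = 0.0,
    model: DemographicModel | str | None = None,
    seed: int = 0,
    population: str = "CEU",
    outgroup_split_years: float = 6e6,
    generation_years: float = DEFAULT_GENERATION,
    N_e: float = DEFAULT_NE,
) -> tuple[HaplotypeAlignment, OutgroupAlignment]:
    """One neutral region plus an aligned outgroup sequence.

    The ingroup is a neutral coalescent sample; the outgroup extends one
    lineage to the species split, so fixed differences accrue as
    Poisson(2 mu t L) with t the split in generations (the same two-lineage
    clock the mutation-rate calibration inverts). Deterministic per seed.
    """
    if model is None:
        model = _constant_model(N_e)
    rng = np.random.default_rng(seed)
    params = SimParams(n=n, L=L, reps=1, seed=int(rng.integers(1, 2**31 - 1)),
                       theta=theta, mu=mu, rho=rho)
    sim = simulate_neutral(params, model, keep_alignments=True)
    aln = sim.alignments[0]
    aln = HaplotypeAlignment(
        region=Region("synth", 0, L, f"neutral_seed{seed}"),
        haplotypes=aln.haplotypes, positions=aln.positions,
        populations=np.array([population] * n, dtype=object),
        alleles=list(aln.alleles))

    mu_rate, _ = params.rates(
        sim.model.present_size(sim.model.populations[0]))
    t_gen = outgroup_split_years / generation_years
    n_fixed = rng.poisson(2.0 * mu_rate * t_gen * L)
    variant = set(int(p) for p in aln.positions)
    free = np.array(sorted(set(range(L)) - variant))
    n_fixed = min(n_fixed, free.size)
    fixed_pos = rng.choice(free, size=n_fixed, replace=False)
    out = np.full(L, "A", dtype="U1")
    out[fixed_pos] = "G"
    # outgroup carries the ancestral (code 0) allele at polymorphic sites
    for p, alleles in zip(aln.positions, aln.alleles):
        out[int(p)] = alleles[0]
    og = attach_outgroup(aln, "".join(out))
    return aln, og


def generate_reference_panel(
    count: int,
    window_bp: int = 5000,
    n: int = 40,
    theta_mean: float = 8e-4,
    theta_sigma: float = 0.5,
    fixed_theta: bool = False,
    model: DemographicModel | str | None = None,
    seed: int = 0,
) -> list[HaplotypeAlignment]:
    """Independent neutral windows emulating a reference panel.

    Per-window per-site theta is log-normal around ``theta_mean`` (on the
    natural scale) to mimic inter-locus mutation/diversity-rate variation;
    ``fixed_theta`` collapses the distribution to the mean so only
    coalescent variance remains.
    """
    if count < 20:
        raise ValueError("a usable panel needs >= 20 windows")
    rng = np.random.default_rng(seed)
    if model is None:
        model = _constant_model(DEFAULT_NE)
    out = []
    for i in range(count):
        if fixed_theta:
            theta_site = theta_mean
        else:
            theta_site = float(rng.lognormal(
                mean=math.log(theta_mean) - 0.5 * theta_sigma**2,
                sigma=theta_sigma))
        params = SimParams(n=n, L=window_bp, reps=1,
                           seed=int(rng.integers(1, 2**31 - 1)),
                           theta=theta_site * window_bp)
        sim = simulate_neutral(params, model, keep_alignments=True)
        aln = sim.alignments[0]
        out.append(HaplotypeAlignment(
            region=Region("panel", 0, window_bp, f"win{i}"),
            haplotypes=aln.haplotypes, positions=aln.positions,
            populations=aln.populations, alleles=list(aln.alleles)))
    return out


def generate_balanced_region(
    spec: BalancedRegionSpec,
) -> tuple[HaplotypeAlignment, dict]:
    """A region whose genealogy has 2-3 deep clades (the balancing-selection
    shape), with exact truth.

    Each clade is an independent neutral coalescent sample; clade MRCAs are
    joined at the specified split times and Poisson mutations dropped on
    the joining branches, so clade-partitioning variants segregate at the
    clade frequencies. The truth dict records the realized TMRCA and the
    clade label of every haplotype.
    """
    rng = np.random.default_rng(spec.seed)
    pops = list(spec.n)
    counts = np.zeros((len(pops), spec.clade_count), dtype=int)
    for pi, pop in enumerate(pops):
        freqs = spec.clade_frequencies[pop]
        raw = [f * spec.n[pop] for f in freqs]
        counts[pi] = [int(round(x)) for x in raw]
        drift = spec.n[pop] - counts[pi].sum()
        counts[pi, int(np.argmax(freqs))] += drift
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("every clade needs at least one sampled haplotype")

    t_gen = [t / spec.generation_years for t in spec.split_times_years]

    clade_blocks, clade_tmrcas = [], []
    for c in range(spec.clade_count):
        n_c = int(counts[:, c].sum())
        if n_c == 1:
            clade_blocks.append(np.zeros((1, 0), dtype=np.int8))
            clade_tmrcas.append(0.0)
            continue
        params = SimParams(n=n_c, L=spec.L, reps=1,
                           seed=int(rng.integers(1, 2**31 - 1)),
                           mu=spec.mu, rho=spec.rho)
        sim = simulate_neutral(params, _constant_model(spec.N_e),
                               keep_alignments=True)
        clade_blocks.append(sim.alignments[0].haplotypes)
        clade_tmrcas.append(float(sim.stats["tmrca_gen"].iloc[0]))

    # stem mutations: clade roots up to their joins
    if spec.clade_count == 2:
        stems = [(0, max(0.0, t_gen[0] - clade_tmrcas[0])),
                 (1, max(0.0, t_gen[0] - clade_tmrcas[1]))]
        inner_join = None
        realized = max(t_gen[0], *clade_tmrcas)
    else:
        t01, t_root = t_gen
        if t_root < t01:
            raise ValueError("root split must be at least the inner split")
        stems = [(0, max(0.0, t01 - clade_tmrcas[0])),
                 (1, max(0.0, t01 - clade_tmrcas[1])),
                 (2, max(0.0, t_root - clade_tmrcas[2]))]
        inner_join = max(0.0, t_root - t01)  # branch carrying clades 0+1
        realized = max(t_root, *clade_tmrcas)

    clade_sizes = [b.shape[0] for b in clade_blocks]
    offsets = np.concatenate([[0], np.cumsum(clade_sizes)])
    n_total = int(offsets[-1])

    columns = []
    for c, block in enumerate(clade_blocks):
        for j in range(block.shape[1]):
            col = np.zeros(n_total, dtype=np.int8)
            col[offsets[c]:offsets[c + 1]] = block[:, j]
            columns.append(col)
    for c, stem_len in stems:
        k = rng.poisson(spec.mu * spec.L * stem_len)
        for _ in range(k):
            col = np.zeros(n_total, dtype=np.int8)
            col[offsets[c]:offsets[c + 1]] = 1
            columns.append(col)
    if inner_join:
        k = rng.poisson(spec.mu * spec.L * inner_join)
        for _ in range(k):
            col = np.zeros(n_total, dtype=np.int8)
            col[offsets[0]:offsets[2]] = 1
            columns.append(col)

    S = len(columns)
    if S > spec.L:
        raise ValueError("more mutations than sites; increase L or lower mu")
    positions = np.sort(rng.choice(spec.L, size=S, replace=False))
    matrix = (np.column_stack(columns) if S else
              np.zeros((n_total, 0), dtype=np.int8))

    populations = np.empty(n_total, dtype=object)
    clade_labels = np.empty(n_total, dtype=int)
    cursor = offsets[:-1].copy()
    for pi, pop in enumerate(pops):
        for c in range(spec.clade_count):
            k = counts[pi, c]
            populations[cursor[c]:cursor[c] + k] = pop
            clade_labels[offsets[c]:offsets[c + 1]] = c
            cursor[c] += k

    aln = HaplotypeAlignment(
        region=Region("synth", 0, spec.L, f"balanced_seed{spec.seed}"),
        haplotypes=matrix, positions=positions, populations=populations,
        alleles=["AC"] * S)
    truth = {
        "tmrca_gen": realized,
        "tmrca_years": realized * spec.generation_years,
        "split_times_years": list(spec.split_times_years),
        "clade_tmrcas_gen": clade_tmrcas,
        "clade_labels": clade_labels.tolist(),
        "seed": spec.seed,
    }
    return aln, truth


def thin_singletons(aln: HaplotypeAlignment, spec: ThinningSpec) -> HaplotypeAlignment:
    """Drop each singleton site independently with ``p_drop_singleton`` —
    the low-coverage undercalling model. Non-singleton sites are untouched."""
    rng = np.random.default_rng(spec.seed)
    keep = np.ones(aln.m, dtype=bool)
    for j in range(aln.m):
        col = aln.haplotypes[:, j]
        called = col[col != MISSING]
        counts = np.bincount(called.astype(int))
        if np.any(counts[counts > 0] == 1):
            keep[j] = rng.uniform() >= spec.p_drop_singleton
    return HaplotypeAlignment(
        region=aln.region,
        haplotypes=aln.haplotypes[:, keep],
        positions=aln.positions[keep],
        populations=aln.populations,
        sample_ids=list(aln.sample_ids),
        alleles=[aln.alleles[j] for j in np.flatnonzero(keep)],
    )


def generate_hka_dataset(
    locus_count: int = 17,
    theta: float | list[float] = 1e-3,
    T: float = 12.0,
    k_map: dict[str, float] | None = None,
    n: int = 40,
    L: float = 5000.0,
    seed: int = 0,
    genealogical_variance: bool = False,
) -> list:
    """Poisson HKA locus table under chosen theta, T and selection k.

    S_i ~ Poisson(k_i theta_i L a_{n-1}), D_i ~ Poisson(theta_i L (T+1));
    loci are named locus00, locus01, ... and k defaults to 1 everywhere.

    With ``genealogical_variance`` the Poisson rates are themselves drawn
    from the coalescent: the polymorphism rate scales with a sampled total
    branch length (adding the (theta L)^2 a2 variance component) and the
    divergence rate with an Exp(1) ancestral coalescence time (adding
    (theta L)^2) — the full variances of the classic HKA model.
    """
    from balsel.diversity import harmonic
    from balsel.hka import HKALocus

    if locus_count < 2:
        raise ValueError("need >= 2 loci")
    rng = np.random.default_rng(seed)
    thetas = (list(theta) if isinstance(theta, (list, tuple, np.ndarray))
              else [float(theta)] * locus_count)
    if len(thetas) != locus_count:
        raise ValueError("theta list length must equal locus_count")
    k_map = k_map or {}
    a = harmonic(n - 1)
    loci = []
    for i, th in enumerate(thetas):
        name = f"locus{i:02d}"
        k = float(k_map.get(name, 1.0))
        if genealogical_variance:
            # total branch length in 2N units: sum_k k * Exp(k(k-1)/2)
            ks = np.arange(2, n + 1)
            t_total = float(np.sum(ks * rng.exponential(
                2.0 / (ks * (ks - 1.0)))))
            S = int(rng.poisson(k * th * L * t_total / 2.0))
            D = int(rng.poisson(th * L * (T + rng.exponential(1.0))))
        else:
            S = int(rng.poisson(k * th * L * a))
            D = int(rng.poisson(th * L * (T + 1.0)))
        loci.append(HKALocus(name=name, S=S, D=D, L_poly=L, L_div=L, n=n))
    return loci


def write_region_bundle(aln: HaplotypeAlignment, out_dir: str | Path,
                        og: OutgroupAlignment | None = None,
                        truth: dict | None = None) -> dict[str, Path]:
    """Write a generated region in the formats the readers consume:
    FASTA haplotypes, TSV pop map, BED region, optional outgroup FASTA and
    truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = aln.region.name or "region"
    paths = {
        "fasta": out_dir / f"{name}.fa",
        "pop_map": out_dir / f"{name}.popmap.tsv",
        "bed": out_dir / f"{name}.bed",
    }
    write_haplotype_fasta(aln, paths["fasta"])
    with open(paths["pop_map"], "w") as fh:
        for sid, pop in zip(aln.sample_ids, aln.populations):
            fh.write(f"{sid}\t{pop}\n")
    with open(paths["bed"], "w") as fh:
        r = aln.region
        fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
    if og is not None:
        paths["outgroup"] = out_dir / f"{name}.outgroup.fa"
        seq = "".join(b if b else "N" for b in og.outgroup_allele)
        with open(paths["outgroup"], "w") as fh:
            fh.write(f">outgroup\n{seq}\n")
    if truth is not None:
        paths["truth"] = out_dir / f"{name}.truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
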