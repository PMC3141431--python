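"""End-to-end scan orchestration and report generation.

``run_scan`` ties the modules together for a set of regions: diversity
summaries, SFS neutrality tests, empirical percentile ranks against a
reference panel, coalescent-simulation p-values, and optional MLHKA and
genealogy blocks. Reports are written as TSV/JSON with a manifest
(seed, config hash, package version) so any run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import balsel
from balsel import coalsim, genealogy, hka as hka_mod, reference
from balsel.diversity import diversity_summary, divergence, sliding_stats
from balsel.neutrality import all_statistics
from balsel.regionio import (
    HaplotypeAlignment,
    Region,
    attach_outgroup,
    read_bed,
    read_haplotype_fasta,
    read_pop_map,
    read_vcf_region,
)

logger = logging.getLogger(__name__)

STATISTICS = ("D_T", "Dstar", "Fstar")


@dataclass
class RegionInput:
    """One region's input files (or an in-memory alignment)."""

    name: str
    fasta: str | None = None
    pop_map: str | None = None
    outgroup_fasta: str | None = None
    alignment: HaplotypeAlignment | None = None
    outgroup_seq: str | None = None

    def load(self) -> tuple[HaplotypeAlignment, str | None]:
        if self.alignment is not None:
            return self.alignment, self.outgroup_seq
        if self.fasta is None or self.pop_map is None:
            raise ValueError(f"region {self.name}: need fasta + pop_map")
        aln = read_haplotype_fasta(self.fasta, self.pop_map)
        out = None
        if self.outgroup_fasta:
            from Bio import SeqIO
            rec = next(SeqIO.parse(self.outgroup_fasta, "fasta"))
            out = str(rec.seq)
        return aln, out


@dataclass
class ScanConfig:
    """Configuration of a full balancing-selection scan."""

    regions: list[RegionInput]
    seed: int = 1
    populations: list[str] | None = None
    reference_panel: reference.ReferencePanel | str | None = None
    demographic_model: str = "constant"
    sim_reps: int = 1000
    outgroup_split_my: float = 6.0
    generation_years: float = 25.0
    mlhka_loci: list | None = None          # reference HKALocus list
    mlhka_selected: list[str] | None = None
    genealogy_enabled: bool = False
    ld_min_r2: float = 0.5
    network_epsilon: int = 0
    tmrca_method: str = "moment"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.sim_reps < 100:
            raise ValueError("sim_reps must be >= 100 for usable p-values")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()
                   if k not in ("regions", "reference_panel", "mlhka_loci")}
        payload["regions"] = [r.name for r in self.regions]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _null_theta(aln: HaplotypeAlignment, og, config: ScanConfig,
                present_size: float) -> float:
    """Region-total theta for the null simulations: outgroup-calibrated mu
    when divergence is available, otherwise the observed Watterson value."""
    if og is not None:
        d = divergence(og).d_raw
        if d > 0:
            mu = coalsim.calibrate_mu(d, config.outgroup_split_my * 1e6,
                                      config.generation_years)
            return 4.0 * present_size * mu * aln.L
    logger.info("no usable outgroup for %s: null theta from Watterson",
                aln.region.name)
    return max(diversity_summary(aln).theta_w, 1e-6) * aln.L


def run_scan(config: ScanConfig) -> dict:
    """Run the full scan; returns the report bundle as a dict of frames.

    Per region x population: L(kb), S, theta_W and pi (x 1e-4), the three
    SFS statistics each with empirical rank (if a panel is configured) and
    coalescent-simulation p; optional MLHKA and genealogy blocks; a
    manifest with seed, versions and config hash.
    """
    panel = config.reference_panel
    if isinstance(panel, (str, Path)):
        panel = reference.ReferencePanel.from_tsv(panel)
    model = coalsim.demographic_preset(config.demographic_model)
    present = model.present_size(model.populations[0])
    rng = np.random.default_rng(config.seed)

    rows, genealogy_block = [], {}
    for region_input in config.regions:
        aln, out_seq = region_input.load()
        og_full = attach_outgroup(aln, out_seq) if out_seq else None
        pops = config.populations or sorted(set(aln.populations))
        for pop in pops:
            if (aln.populations == pop).sum() < 4:
                logger.warning("region %s: population %s has < 4 haplotypes; "
                               "skipped", region_input.name, pop)
                continue
            sub = aln.subset_population(pop)
            summ = diversity_summary(sub)
            stats = all_statistics(sub)
            row = {"region": region_input.name, "population": pop,
                   "L_kb": sub.L / 1000.0, "n": sub.n, "S": summ.S,
                   "theta_w_e4": summ.theta_w_report, "pi_e4": summ.pi_report}
            if panel is not None:
                row["theta_w_rank"] = reference.percentile_rank(
                    summ.theta_w, panel, "theta_w")
                row["pi_rank"] = reference.percentile_rank(summ.pi, panel, "pi")
            theta0 = _null_theta(sub, og_full, config, present)
            sims = coalsim.simulate_neutral(
                coalsim.SimParams(n=sub.n, L=sub.L, reps=config.sim_reps,
                                  seed=int(rng.integers(1, 2**31 - 1)),
                                  theta=theta0),
                model)
            for stat in STATISTICS:
                value = stats[stat]
                row[stat] = value
                if np.isfinite(value):
                    if panel is not None:
                        row[f"{stat}_rank"] = reference.percentile_rank(
                            value, panel, stat)
                    row[f"{stat}_p"] = coalsim.simulation_pvalue(
                        value, sims, stat, tail="upper")
            rows.append(row)

        if config.genealogy_enabled:
            screen = genealogy.four_gamete_screen(aln)
            net = genealogy.median_joining_network(
                screen.filtered, epsilon=config.network_epsilon)
            block = {"removed_sites": screen.removed_sites,
                     "removed_haplotypes": screen.removed_haplotypes,
                     "network_nodes": net.graph.number_of_nodes(),
                     "network_total_weight": net.total_weight}
            if og_full is not None:
                d = divergence(og_full).d_raw
                if d > 0:
                    mu = coalsim.calibrate_mu(
                        d, config.outgroup_split_my * 1e6,
                        config.generation_years)
                    est = genealogy.estimate_tmrca(
                        screen.filtered, mu=mu,
                        generation_years=config.generation_years,
                        method=config.tmrca_method,
                        seed=int(rng.integers(1, 2**31 - 1)))
                    block["tmrca_years"] = est.t_years
                    block["tmrca_scaled"] = est.t_scaled
                    block["N_e"] = est.N_e
            genealogy_block[region_input.name] = block

    report: dict = {"table": pd.DataFrame(rows)}
    if config.mlhka_loci and config.mlhka_selected:
        null_fit = hka_mod.mlhka_fit(config.mlhka_loci, set())
        alt_fit = hka_mod.mlhka_fit(config.mlhka_loci,
                                    set(config.mlhka_selected))
        report["mlhka"] = {
            "k": {nm: alt_fit.k[nm] for nm in config.mlhka_selected},
            "p": hka_mod.mlhka_lrt(null_fit, alt_fit),
            "logL_null": null_fit.logL, "logL_alt": alt_fit.logL,
        }
        x2, p_chisq = hka_mod.hka_chisq(config.mlhka_loci)
        report["hka_chisq"] = {"X2": x2, "p": p_chisq}
    if genealogy_block:
        report["genealogy"] = genealogy_block
    report["manifest"] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": balsel.__version__,
        "sim_reps": config.sim_reps,
        "demographic_model": config.demographic_model,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["table"].to_csv(out / "scan_table.tsv", sep="\t", index=False,
                               float_format="%.6g")
        payload = {k: v for k, v in report.items() if k != "table"}
        (out / "scan_report.json").write_text(json.dumps(payload, indent=1,
                                                         default=str))
    return report


def run_window_scan(
    vcf: str,
    bed: str,
    window_bp: int,
    step_bp: int,
    pop_map: str,
    population: str | None = None,
    out_prefix: str | None = None,
    plot: bool = False,
) -> pd.DataFrame:
    """Sliding theta_W/pi windows over VCF regions (BED-defined).

    Writes ``<prefix>.tsv`` and a browser-loadable ``<prefix>.bed`` when a
    prefix is given (plus ``<prefix>.png`` with ``plot=True``); returns
    the combined window table.
    """
    regions = read_bed(bed)
    pops = read_pop_map(pop_map)
    frames = []
    for region in regions:
        aln = read_vcf_region(vcf, region, pops)
        if population is not None:
            aln = aln.subset_population(population)
        if window_bp > aln.L:
            logger.warning("window %d > region %s length %d; skipped",
                           window_bp, region.name, aln.L)
            continue
        df = sliding_stats(aln, window_bp, step_bp)
        df.insert(0, "region", region.name or region.chrom)
        frames.append(df)
    if not frames:
        logger.warning("no region admitted the requested window size")
        return pd.DataFrame(columns=["region", "chrom", "start", "end",
                                     "name", "S", "theta_w", "pi"])
    table = pd.concat(frames, ignore_index=True)
    if out_prefix:
        table.to_csv(f"{out_prefix}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        with open(f"{out_prefix}.bed", "w") as fh:
            for row in table.itertuples():
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.name}\t{row.theta_w:.6g}\n")
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(8, 3))
            mid = (table.start + table.end) / 2
            ax.plot(mid, table.theta_w * 1e4, color="red", label=r"$\theta_W$")
            ax.plot(mid, table.pi * 1e4, color="blue", label=r"$\pi$")
            ax.set_xlabel("position (bp)")
            ax.set_ylabel(r"per-site diversity ($\times 10^{-4}$)")
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(f"{out_prefix}.png", dpi=120)
            plt.close(fig)
    return table
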