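"""Diversity estimators, divergence, sliding windows and pairwise LD.

Per-site estimates are stored unscaled; reports multiply by 1e4 to match
the conventional x1e-4 presentation of resequencing-survey tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from balsel.regionio import (
    MISSING,
    HaplotypeAlignment,
    OutgroupAlignment,
    Region,
)

logger = logging.getLogger(__name__)

REPORT_SCALE = 1e4


def harmonic(n: int, power: int = 1) -> float:
    """``sum_{i=1}^{n} 1/i**power`` (the a1/a2 coefficients use n-1 terms)."""
    i = np.arange(1, n + 1)
    return float(np.sum(1.0 / i.astype(float) ** power))


@dataclass(frozen=True)
class DiversitySummary:
    """Region-level diversity summary.

    ``theta_w`` and ``pi`` are per-site; ``eta`` counts mutations under the
    infinite-sites convention (a triallelic site contributes 2), ``eta_s``
    counts alleles observed exactly once.
    """

    S: int
    eta: int
    eta_s: int
    theta_w: float
    pi: float
    n: int
    L: int

    @property
    def theta_w_report(self) -> float:
        return self.theta_w * REPORT_SCALE

    @property
    def pi_report(self) -> float:
        return self.pi * REPORT_SCALE


@dataclass(frozen=True)
class DivergenceSummary:
    fixed_diffs: int
    aligned_L: int
    d_raw: float
    d_jc: float | None = None


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's per-site estimate ``S / (a_{n-1} L)``."""
    if n < 2:
        raise ValueError(f"need n >= 2 chromosomes, got {n}")
    if L <= 0:
        raise ValueError(f"need L > 0, got {L}")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return 0.0
    return S / (harmonic(n - 1) * L)


def _column_allele_counts(col: np.ndarray) -> np.ndarray:
    """Counts of each allele code (0..max) among non-missing calls."""
    called = col[col != MISSING]
    return np.bincount(called.astype(np.int64), minlength=int(called.max()) + 1)


def site_pi(col: np.ndarray) -> float:
    """Average pairwise mismatch at one site (unbiased, any allele number).

    Uses the non-missing allele count ``n_i`` at the site, so partially
    missing columns contribute their called subsample.
    """
    counts = _column_allele_counts(col)
    n_i = counts.sum()
    if n_i < 2:
        return 0.0
    return float(1.0 - np.sum(counts * (counts - 1)) / (n_i * (n_i - 1)))


def diversity_summary(aln: HaplotypeAlignment) -> DiversitySummary:
    """S, eta, eta_s, Watterson's theta and pi for one alignment.

    pi is the average over all haplotype pairs of the per-site mismatch
    count divided by L (equivalently the sum over sites of unbiased
    heterozygosity over L); a triallelic site counts any allele mismatch.
    """
    S = aln.m
    eta = eta_s = 0
    pi_total = 0.0
    for j in range(aln.m):
        counts = _column_allele_counts(aln.haplotypes[:, j])
        n_alleles = int((counts > 0).sum())
        eta += n_alleles - 1
        # singleton mutations: alleles called exactly once, capped at the
        # mutation count so a doubleton split 1/1 counts one singleton
        eta_s += min(int(np.sum(counts == 1)), n_alleles - 1)
        pi_total += site_pi(aln.haplotypes[:, j])
    return DiversitySummary(
        S=S,
        eta=eta,
        eta_s=eta_s,
        theta_w=watterson_theta(S, aln.n, aln.L),
        pi=pi_total / aln.L,
        n=aln.n,
        L=aln.L,
    )


def total_pi(aln: HaplotypeAlignment) -> float:
    """Region-total average pairwise differences (pi * L)."""
    return sum(site_pi(aln.haplotypes[:, j]) for j in range(aln.m))


def divergence(og: OutgroupAlignment, jukes_cantor: bool = False) -> DivergenceSummary:
    """Per-site divergence from fixed differences with the outgroup.

    ``aligned_L`` excludes unalignable sites. The Jukes-Cantor correction
    ``-(3/4) ln(1 - 4d/3)`` is optional; raw divergence is the default used
    for HKA and for mutation-rate calibration.
    """
    fixed = og.fixed_differences
    aligned_L = og.aligned_length
    if aligned_L == 0:
        raise ValueError("no alignable sites")
    d_raw = fixed / aligned_L
    d_jc = None
    if jukes_cantor:
        if d_raw >= 0.75:
            raise ValueError(f"Jukes-Cantor correction undefined for d={d_raw:.3f}")
        d_jc = float(-0.75 * np.log1p(-4.0 * d_raw / 3.0))
    return DivergenceSummary(fixed_diffs=fixed, aligned_L=aligned_L,
                             d_raw=d_raw, d_jc=d_jc)


def sliding_stats(aln: HaplotypeAlignment, window_bp: int, step_bp: int) -> pd.DataFrame:
    """theta_W and pi in left-aligned tiling windows.

    Windows cover ``[start, start+window)``, advancing by ``step_bp``;
    the count is ``floor((L - window)/step) + 1``. Per-window L is the
    window size.
    """
    if window_bp > aln.L:
        raise ValueError(f"window {window_bp} exceeds region length {aln.L}")
    if step_bp <= 0:
        raise ValueError("step must be positive")
    n_windows = (aln.L - window_bp) // step_bp + 1
    rows = []
    for w in range(n_windows):
        start = aln.region.start + w * step_bp
        win = Region(aln.region.chrom, start, start + window_bp,
                     f"{aln.region.name}_w{w}")
        sub = aln.subset_window(win)
        summ = diversity_summary(sub)
        rows.append({"chrom": win.chrom, "start": win.start, "end": win.end,
                     "name": win.name, "S": summ.S,
                     "theta_w": summ.theta_w, "pi": summ.pi})
    return pd.DataFrame(rows)


def pairwise_ld(aln: HaplotypeAlignment) -> pd.DataFrame:
    """D' and r^2 for every pair of common biallelic sites.

    Computed from phased haplotype (gamete) counts; monomorphic columns
    cannot occur in the matrix, triallelic sites are skipped with a warning.
    Returns a long-format frame with one row per ordered pair i < j.
    """
    biallelic = [j for j in range(aln.m)
                 if _column_allele_counts(aln.haplotypes[:, j]).size == 2]
    if len(biallelic) < aln.m:
        warnings.warn(f"skipping {aln.m - len(biallelic)} non-biallelic sites "
                      "in LD computation", stacklevel=2)
    if len(biallelic) < 2:
        raise ValueError("need >= 2 biallelic sites for LD")
    rows = []
    H = aln.haplotypes
    for a_idx, i in enumerate(biallelic):
        for j in biallelic[a_idx + 1:]:
            ok = (H[:, i] != MISSING) & (H[:, j] != MISSING)
            x, y = H[ok, i].astype(float), H[ok, j].astype(float)
            pA, pB = x.mean(), y.mean()
            if pA in (0.0, 1.0) or pB in (0.0, 1.0):
                continue  # monomorphic within the called subset
            pAB = float((x * y).mean())
            D = pAB - pA * pB
            if D >= 0:
                dmax = min(pA * (1 - pB), (1 - pA) * pB)
            else:
                dmax = min(pA * pB, (1 - pA) * (1 - pB))
            dprime = D / dmax if dmax > 0 else 0.0
            r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
            rows.append({"pos_i": int(aln.positions[i]),
                         "pos_j": int(aln.positions[j]),
                         "D": D, "Dprime": dprime, "r2": r2})
    return pd.DataFrame(rows)
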