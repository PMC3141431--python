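"""Polymorphism-versus-divergence tests: multilocus HKA and
maximum-likelihood HKA.

Under neutrality the ratio of within-species polymorphism to
between-species divergence is the same at every locus; an excess of
polymorphism at a locus is the HKA signature of balancing selection. The
classic test fits per-locus diversity parameters theta_i and a common
divergence time T by moment equations and measures departure with a
chi-square statistic. The maximum-likelihood variant models counts as
Poisson,

    S_i ~ Poisson(k_i theta_i L_i a(n_i)),   D_i ~ Poisson(theta_i L_i (T+1)),

with a selection parameter k_i free at designated loci (k = 1 elsewhere);
k > 1 means an excess of diversity relative to divergence. Significance
comes from a likelihood-ratio test with df = number of selected loci.

Divergence is to a single outgroup sequence; E[D] = theta L (T + 1), the
"+1" absorbing ancestral polymorphism (two lineages of expected depth 2N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from balsel.diversity import harmonic

logger = logging.getLogger(__name__)

_LOGL_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Numerical maximization failed; carries optimizer diagnostics."""


@dataclass(frozen=True)
class HKALocus:
    """Observed counts for one locus.

    ``L_poly``/``L_div`` are the bp surveyed for polymorphism and aligned
    for divergence (they may differ when outgroup alignment has gaps).
    """

    name: str
    S: int
    D: int
    L_poly: float
    L_div: float
    n: int

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise ValueError("counts must be non-negative")
        if self.L_poly <= 0 or self.L_div <= 0:
            raise ValueError("lengths must be positive")
        if self.n < 2:
            raise ValueError("need n >= 2 chromosomes")

    @property
    def a_n(self) -> float:
        return harmonic(self.n - 1)


@dataclass
class MLHKAFit:
    """Maximum-likelihood HKA fit.

    ``theta`` maps locus name to the per-locus diversity parameter (per bp,
    in 2N units), ``T`` is the divergence time in 2N units, ``k`` holds the
    selection parameter for each selected locus (all 1 in a null fit).
    """

    theta: dict[str, float]
    T: float
    k: dict[str, float]
    logL: float
    selected: frozenset[str]
    converged: bool = True
    restarts_used: int = 0


# ---------------------------------------------------------------------------
# classic multilocus HKA
# ---------------------------------------------------------------------------

def _hka_moment_fit(loci: list[HKALocus]) -> tuple[np.ndarray, float]:
    """Fit theta_i (per locus total, per bp) and T by the moment equations

    S_i + D_i = theta_i (L_p a_i + L_d (T+1)),  sum D_i = (T+1) sum theta_i L_d,

    solved by fixed-point iteration on T.
    """
    S = np.array([loc.S for loc in loci], dtype=float)
    D = np.array([loc.D for loc in loci], dtype=float)
    Lp = np.array([loc.L_poly for loc in loci], dtype=float)
    Ld = np.array([loc.L_div for loc in loci], dtype=float)
    a = np.array([loc.a_n for loc in loci], dtype=float)
    if np.all(S + D == 0):
        raise ValueError("degenerate fit: all loci have zero counts")

    Tp1 = max(D.sum(), 1.0) / max(S.sum() / a.mean(), 1e-9)  # rough start
    for _ in range(500):
        theta = (S + D) / (Lp * a + Ld * Tp1)
        denom = float(np.sum(theta * Ld))
        if denom <= 0:
            raise ValueError("degenerate fit: zero total diversity")
        Tp1_new = D.sum() / denom
        if abs(Tp1_new - Tp1) < 1e-12 * max(1.0, Tp1):
            Tp1 = Tp1_new
            break
        Tp1 = Tp1_new
    theta = (S + D) / (Lp * a + Ld * Tp1)
    return theta, Tp1 - 1.0


def hka_chisq(loci: list[HKALocus]) -> tuple[float, float]:
    """Classic multilocus HKA goodness-of-fit.

    X^2 sums squared deviations of S and D from their fitted expectations,
    scaled by the neutral-model variances
    Var[S_i] = E[S_i] + (theta_i L_p)^2 b(n_i) and
    Var[D_i] = E[D_i] + (theta_i L_d)^2; p from chi-square with
    (#loci - 1) degrees of freedom.
    """
    if len(loci) < 2:
        raise ValueError("need >= 2 loci")
    theta, T = _hka_moment_fit(loci)
    x2 = 0.0
    for i, loc in enumerate(loci):
        th_Lp = theta[i] * loc.L_poly
        th_Ld = theta[i] * loc.L_div
        ES = th_Lp * loc.a_n
        ED = th_Ld * (T + 1.0)
        b = harmonic(loc.n - 1, power=2)
        varS = ES + th_Lp ** 2 * b
        varD = ED + th_Ld ** 2
        if varS > 0:
            x2 += (loc.S - ES) ** 2 / varS
        if varD > 0:
            x2 += (loc.D - ED) ** 2 / varD
    df = len(loci) - 1
    p = float(stats.chi2.sf(x2, df))
    return float(x2), p


# ---------------------------------------------------------------------------
# maximum-likelihood HKA
# ---------------------------------------------------------------------------

def _profile_loglik(loci: list[HKALocus], Tp1: float,
                    k: dict[str, float]) -> tuple[float, np.ndarray]:
    """Log-likelihood with theta_i profiled out in closed form.

    Given T and k the per-locus Poisson likelihood is maximised at
    theta_i = (S_i + D_i) / (k_i L_p a_i + L_d (T+1)).
    """
    S = np.array([loc.S for loc in loci], dtype=float)
    D = np.array([loc.D for loc in loci], dtype=float)
    Lp = np.array([loc.L_poly for loc in loci], dtype=float)
    Ld = np.array([loc.L_div for loc in loci], dtype=float)
    a = np.array([loc.a_n for loc in loci], dtype=float)
    kv = np.array([k.get(loc.name, 1.0) for loc in loci], dtype=float)

    rate_poly_coeff = kv * Lp * a
    rate_div_coeff = Ld * Tp1
    theta = (S + D) / (rate_poly_coeff + rate_div_coeff)
    lam_S = theta * rate_poly_coeff
    lam_D = theta * rate_div_coeff
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (np.where(S > 0, S * np.log(lam_S), 0.0) - lam_S
              + np.where(D > 0, D * np.log(lam_D), 0.0) - lam_D)
    return float(np.sum(ll)), theta


def mlhka_fit(loci: list[HKALocus], selected: set[str] | frozenset[str],
              n_restarts: int = 8, seed: int = 0) -> MLHKAFit:
    """Fit the MLHKA model by deterministic multi-start maximization.

    Optimizes (log(T+1), log k_selected) with Nelder-Mead from several
    seeded starting points (theta_i profiled analytically); an empty
    ``selected`` set gives the null fit with all k = 1.
    """
    names = [loc.name for loc in loci]
    selected = frozenset(selected)
    unknown = selected - set(names)
    if unknown:
        raise KeyError(f"selected loci not in table: {sorted(unknown)}")
    if selected and not (set(names) - selected):
        raise ValueError("need at least one unselected reference locus")
    sel = sorted(selected)

    def objective(x: np.ndarray) -> float:
        Tp1 = np.exp(x[0])
        k = {nm: float(np.exp(v)) for nm, v in zip(sel, x[1:])}
        ll, _ = _profile_loglik(loci, Tp1, k)
        return -ll

    # data-driven start: moment-fit T, k from per-locus S/D contrast
    try:
        _, T0 = _hka_moment_fit(loci)
        T0 = max(T0, 0.01)
    except ValueError:
        T0 = 5.0
    x0 = np.array([np.log(T0 + 1.0)] + [0.0] * len(sel))
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0, 1.0, size=x0.size)
                     for _ in range(n_restarts - 1)]

    best, best_x, used, agreeing = -np.inf, None, 0, 0
    for start in starts:
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": _LOGL_TOL,
                                         "maxiter": 20_000})
        used += 1
        if best_x is None or -res.fun > best + _LOGL_TOL:
            best, best_x = -res.fun, res.x
            agreeing = 1
        elif abs(-res.fun - best) < 1e-6:
            agreeing += 1
        # the profiled surface is smooth and low-dimensional; stop once two
        # independent starts agree on the optimum
        if used >= 3 and agreeing >= 2 and np.isfinite(best):
            break
    if best_x is None or not np.isfinite(best):
        raise ConvergenceError(
            f"MLHKA failed to converge after {used} restarts (best logL={best})")

    Tp1 = float(np.exp(best_x[0]))
    k = {nm: float(np.exp(v)) for nm, v in zip(sel, best_x[1:])}
    ll, theta = _profile_loglik(loci, Tp1, k)
    k_full = {nm: k.get(nm, 1.0) for nm in names}
    return MLHKAFit(theta=dict(zip(names, theta.tolist())), T=Tp1 - 1.0,
                    k=k_full, logL=ll, selected=selected,
                    restarts_used=used)


def mlhka_lrt(null_fit: MLHKAFit, alt_fit: MLHKAFit) -> float:
    """Likelihood-ratio p-value for the selected-loci k parameters.

    Lambda = 2 (logL_alt - logL_null) compared to chi-square with
    df = number of selected loci.
    """
    if null_fit.selected:
        raise ValueError("null fit must have no selected loci")
    if set(null_fit.theta) != set(alt_fit.theta):
        raise ValueError("fits compare different locus sets")
    lam = 2.0 * (alt_fit.logL - null_fit.logL)
    if lam < -1e-6:
        raise ConvergenceError(
            f"alternative logL below null ({lam=:.3g}); optimization failed")
    lam = max(lam, 0.0)
    df = len(alt_fit.selected)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(lam, df))


def tajima_band_filter(panel_values: pd.Series | np.ndarray,
                       lower_pct: float = 5.0,
                       upper_pct: float = 95.0) -> np.ndarray:
    """Boolean mask of panel loci whose Tajima's D lies strictly inside the
    [lower, upper] percentile band — the conventional rule for picking
    neutral HKA reference loci from an empirical panel."""
    vals = np.asarray(panel_values, dtype=float)
    finite = np.isfinite(vals)
    lo, hi = np.percentile(vals[finite], [lower_pct, upper_pct])
    return finite & (vals > lo) & (vals < hi)
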