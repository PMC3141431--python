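"""Site-frequency-spectrum neutrality tests.

Tajima's D contrasts pi with Watterson's theta; Fu & Li's starred tests
contrast total mutations (eta) and singleton mutations (eta_s), which are
enriched on external genealogy branches, without requiring an outgroup.
Positive values of all three indicate an excess of intermediate-frequency
variants — the classic signature of balancing selection — while negative
values indicate a singleton/rare-variant excess.

Variance coefficients for D* and F* follow the corrected published
constants (the formulation adopted by the widely used
sequence-analysis libraries) rather than the misprinted originals; the
exact expressions are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from balsel.diversity import diversity_summary, harmonic, total_pi
from balsel.regionio import HaplotypeAlignment


class UndefinedStatisticError(ValueError):
    """Raised when a test statistic is undefined (no segregating sites or
    too few chromosomes)."""


@dataclass(frozen=True)
class SFSConstants:
    """Sample-size-dependent constants for the SFS tests.

    ``a1``/``a2`` are the harmonic sums over n-1 terms; ``b1..e2`` are
    Tajima's variance coefficients; ``c_n``/``d_n`` and the u/v pairs are
    the corrected starred-test coefficients.
    """

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    c_n: float
    d_n: float
    u_dstar: float
    v_dstar: float
    u_fstar: float
    v_fstar: float


@lru_cache(maxsize=None)
def sfs_constants(n: int) -> SFSConstants:
    if n < 4:
        raise UndefinedStatisticError(f"SFS tests need n >= 4, got {n}")
    nf = float(n)
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)

    # Tajima's D
    b1 = (nf + 1) / (3 * (nf - 1))
    b2 = 2 * (nf * nf + nf + 3) / (9 * nf * (nf - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (nf + 2) / (a1 * nf) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)

    # Fu & Li starred coefficients (corrected constants)
    an1 = a1 + 1 / nf  # a_{n+1} in the harmonic series over n terms
    c_n = 2 * (nf * a1 - 2 * (nf - 1)) / ((nf - 1) * (nf - 2))
    d_n = (c_n + (nf - 2) / ((nf - 1) ** 2)
           + (2 / (nf - 1)) * (1.5 - (2 * an1 - 3) / (nf - 2) - 1 / nf))
    v_dstar = ((nf / (nf - 1)) ** 2 * a2 + a1 * a1 * d_n
               - 2 * nf * a1 * (a1 + 1) / ((nf - 1) ** 2)) / (a1 * a1 + a2)
    u_dstar = (nf / (nf - 1)) * (a1 - nf / (nf - 1)) - v_dstar
    v_fstar = (d_n + 2 * (nf * nf + nf + 3) / (9 * nf * (nf - 1))
               - (2 / (nf - 1)) * (4 * a2 - 6 + 8 / nf)) / (a1 * a1 + a2)
    u_fstar = ((nf / (nf - 1) + (nf + 1) / (3 * (nf - 1)) - 4 / (nf * (nf - 1))
                + 2 * (nf + 1) / ((nf - 1) ** 2) * (an1 - 2 * nf / (nf + 1)))
               / a1) - v_fstar

    return SFSConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
                        e1=e1, e2=e2, c_n=c_n, d_n=d_n,
                        u_dstar=u_dstar, v_dstar=v_dstar,
                        u_fstar=u_fstar, v_fstar=v_fstar)


def _summaries(aln: HaplotypeAlignment):
    summ = diversity_summary(aln)
    if summ.S == 0:
        raise UndefinedStatisticError("no segregating sites: statistic undefined")
    return summ, sfs_constants(aln.n), total_pi(aln)


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D from region-total pi and S.

    D = (Pi - S/a1) / sqrt(e1 S + e2 S (S-1)).
    """
    summ, k, pi_tot = _summaries(aln)
    S = summ.S
    var = k.e1 * S + k.e2 * S * (S - 1)
    return float((pi_tot - S / k.a1) / np.sqrt(var))


def fu_li_dstar(aln: HaplotypeAlignment) -> float:
    """Fu & Li's D*: eta versus singleton count eta_s, no outgroup.

    D* = (n/(n-1) eta - a1 eta_s) / sqrt(u_D* eta + v_D* eta^2);
    positive when singletons are depleted relative to neutral expectation.
    """
    summ, k, _ = _summaries(aln)
    n, eta, eta_s = summ.n, summ.eta, summ.eta_s
    num = (n / (n - 1)) * eta - k.a1 * eta_s
    return float(num / np.sqrt(k.u_dstar * eta + k.v_dstar * eta * eta))


def fu_li_fstar(aln: HaplotypeAlignment) -> float:
    """Fu & Li's F*: region-total pi versus singleton count eta_s.

    F* = (Pi - (n-1)/n eta_s) / sqrt(u_F* eta + v_F* eta^2).
    """
    summ, k, pi_tot = _summaries(aln)
    n, eta, eta_s = summ.n, summ.eta, summ.eta_s
    num = pi_tot - ((n - 1) / n) * eta_s
    return float(num / np.sqrt(k.u_fstar * eta + k.v_fstar * eta * eta))


def all_statistics(aln: HaplotypeAlignment) -> dict[str, float]:
    """D_T, D* and F* in one pass; NaN where undefined."""
    out = {}
    for name, fn in (("D_T", tajimas_d), ("Dstar", fu_li_dstar),
                     ("Fstar", fu_li_fstar)):
        try:
            out[name] = fn(aln)
        except UndefinedStatisticError:
            out[name] = float("nan")
    return out
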