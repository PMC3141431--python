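"""Empirical significance against a neutral reference panel.

A reference panel holds per-window summary statistics for a collection of
putatively neutral windows (e.g. 5 kb windows from resequenced genes);
observed region statistics are percentile-ranked against the panel
distribution, values above the 95th percentile being the conventional
empirical-outlier call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from balsel.diversity import diversity_summary
from balsel.neutrality import all_statistics
from balsel.regionio import HaplotypeAlignment

logger = logging.getLogger(__name__)

PANEL_STATISTICS = ("theta_w", "pi", "D_T", "Dstar", "Fstar")
MIN_PANEL_WINDOWS = 20


@dataclass
class ReferencePanel:
    """Per-window statistics of a neutral empirical panel.

    ``windows`` has one row per window with columns window, n, L, S,
    theta_w, pi, D_T, Dstar, Fstar (NaN where a test is undefined, e.g.
    monomorphic windows); NaN rows are excluded from that statistic's rank
    denominator.
    """

    windows: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.windows) < MIN_PANEL_WINDOWS:
            raise ValueError(
                f"reference panel needs >= {MIN_PANEL_WINDOWS} windows, "
                f"got {len(self.windows)}")

    def values(self, statistic: str) -> np.ndarray:
        if statistic not in self.windows.columns:
            raise KeyError(f"statistic {statistic!r} absent from panel "
                           f"(have {list(self.windows.columns)})")
        vals = self.windows[statistic].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# reference panel; provenance={self.provenance}\n")
            self.windows.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferencePanel":
        text = Path(path).read_text().splitlines()
        provenance = "unknown"
        if text and text[0].startswith("#"):
            for token in text[0].lstrip("# ").split(";"):
                if token.strip().startswith("provenance="):
                    provenance = token.strip().split("=", 1)[1]
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(windows=df, provenance=provenance)


def build_reference_panel(
    alignments: Iterable[HaplotypeAlignment],
    provenance: str = "synthetic",
) -> ReferencePanel:
    """Compute the per-window statistic table for a panel of alignments.

    Windows with S=0 carry theta_w=pi=0 and NaN test statistics.
    """
    rows = []
    for idx, aln in enumerate(alignments):
        summ = diversity_summary(aln)
        stats = all_statistics(aln)
        rows.append({"window": aln.region.name or f"win{idx}",
                     "n": summ.n, "L": summ.L, "S": summ.S,
                     "theta_w": summ.theta_w, "pi": summ.pi, **stats})
    if not rows:
        raise ValueError("empty alignment collection")
    return ReferencePanel(windows=pd.DataFrame(rows), provenance=provenance)


def percentile_rank(value: float, panel: ReferencePanel, statistic: str) -> float:
    """Midrank empirical percentile of ``value`` in the panel distribution.

    rank = (#panel values < value + 0.5 * #ties) / #defined values.
    """
    vals = panel.values(statistic)
    if vals.size == 0:
        raise ValueError(f"panel has no defined values for {statistic!r}")
    below = float(np.sum(vals < value))
    ties = float(np.sum(vals == value))
    return (below + 0.5 * ties) / vals.size


def format_rank(rank: float) -> str:
    """Presentation form used in diversity tables: >0.99 / <0.01 capping."""
    if rank > 0.99:
        return ">0.99"
    if rank < 0.01:
        return "<0.01"
    return f"{rank:.2f}"


def comparability_check(panel: ReferencePanel, aln: HaplotypeAlignment) -> None:
    """Warn when test-region n or L differ from the panel windows (the
    standard workflow ranks 2-9 kb regions against 5 kb windows, which is a
    deliberate asymmetry but worth surfacing)."""
    panel_n = panel.windows["n"].unique()
    panel_L = panel.windows["L"].unique()
    if aln.n not in panel_n:
        warnings.warn(f"test region n={aln.n} differs from panel n="
                      f"{sorted(panel_n)}; ranks compare unlike sample sizes",
                      stacklevel=2)
    if aln.L not in panel_L:
        logger.info("test region L=%d vs panel L=%s", aln.L, sorted(panel_L))
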