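"""Per-taxon, per-trait summary statistics in species-description format.

Each (taxon, trait) cell is reported as ``Mean ± SD (Min – Max)`` — the
conventional rendering in taxonomic descriptions — alongside a long-form
numeric table for programmatic use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import PhenotypeMatrix

__all__ = ["SummaryTable", "compute_summary_stats", "format_summary"]


def _fmt(x: float) -> str:
    """Round to <=2 decimals and strip trailing zeros ('7.10' -> '7.1')."""
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return "0" if s == "-0" else s


def format_summary(mean: float, sd: float, vmin: float, vmax: float) -> str:
    """Render ``Mean ± SD (Min – Max)`` with an en-dash range separator."""
    return f"{_fmt(mean)} ± {_fmt(sd)} ({_fmt(vmin)}–{_fmt(vmax)})"


@dataclass
class SummaryTable:
    """Long numeric table plus the wide formatted (taxon x trait) view."""

    long: pd.DataFrame  # taxon, trait, mean, sd, min, max, n, formatted

    @property
    def wide(self) -> pd.DataFrame:
        return self.long.pivot(index="taxon", columns="trait", values="formatted")

    def to_csv(self, path: str | Path) -> None:
        self.wide.to_csv(path)

    def to_csv_long(self, path: str | Path) -> None:
        self.long.to_csv(path, index=False)


def compute_summary_stats(m: PhenotypeMatrix) -> SummaryTable:
    """Mean, sample SD, range and n for every (taxon, numeric trait) cell.

    Cells with zero observations are omitted; a single observation gets
    sd = 0 (n−1 denominator is undefined at n = 1).
    """
    rows = []
    for taxon in m.taxon_levels:
        for trait in m.trait_names:
            v = m.group_values(trait, taxon)
            if v.size == 0:
                continue
            mean = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            vmin, vmax = float(np.min(v)), float(np.max(v))
            rows.append(
                {
                    "taxon": taxon,
                    "trait": trait,
                    "mean": mean,
                    "sd": sd,
                    "min": vmin,
                    "max": vmax,
                    "n": int(v.size),
                    "formatted": format_summary(mean, sd, vmin, vmax),
                }
            )
    return SummaryTable(pd.DataFrame(rows))
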