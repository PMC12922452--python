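"""Diagnostic-trait scan: trait ranges that do not overlap between taxon pairs.

A trait whose observed ranges in two taxa are disjoint permits unambiguous
field identification of those taxa.  Ranges are treated as closed
intervals, so a shared endpoint counts as overlap — conservative, since a
shared observed value defeats a field diagnosis.  Traits that do overlap
for a pair are the ones later examined by the univariate tests.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from .core_data import PhenotypeMatrix

__all__ = ["find_nonoverlapping", "NO_NONOVERLAP_MESSAGE"]

NO_NONOVERLAP_MESSAGE = "No nonoverlapping traits found between any taxon pair."

COLUMNS = ["trait", "taxon_a", "taxon_b", "min_a", "max_a", "min_b", "max_b", "gap"]


def find_nonoverlapping(m: PhenotypeMatrix) -> pd.DataFrame:
    """Scan all taxon pairs x traits for disjoint closed ranges.

    Returns one row per (trait, pair) whose ranges are strictly disjoint,
    with ``gap`` = distance between the closer endpoints.  Pairs where
    either taxon has no observation of the trait are skipped.
    """
    rows = []
    for trait in m.trait_names:
        for a, b in combinations(m.taxon_levels, 2):
            va, vb = m.group_values(trait, a), m.group_values(trait, b)
            if va.size == 0 or vb.size == 0:
                continue
            min_a, max_a = float(va.min()), float(va.max())
            min_b, max_b = float(vb.min()), float(vb.max())
            if max_a < min_b:
                gap = min_b - max_a
            elif max_b < min_a:
                gap = min_a - max_b
            else:
                continue
            rows.append(dict(zip(COLUMNS, (trait, a, b, min_a, max_a, min_b, max_b, gap))))
    return pd.DataFrame(rows, columns=COLUMNS)
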