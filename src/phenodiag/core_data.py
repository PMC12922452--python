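"""Input parsing, validation and bookkeeping shared by every analysis stage.

The central container is :class:`PhenotypeMatrix`: one row per individual,
one numeric column per trait, plus a taxon (species/population) label per
row.  Traits are classified as *mensural* (continuous measurements such as
lengths and angles, which typically scale with body size) or *meristic*
(integer counts such as scale rows), a distinction that drives plot style
and allometric correction but not the statistics themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeMatrix",
    "PhenotypeError",
    "read_phenotype_csv",
    "classify_trait",
    "assign_colors",
    "DEFAULT_PALETTE",
]


class PhenotypeError(ValueError):
    """Raised for malformed phenotype input (named error per contract)."""


#: Fixed 12-colour qualitative palette (hex), cycled when taxa exceed it.
DEFAULT_PALETTE: tuple[str, ...] = (
    "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c", "#fb9a99", "#e31a1c",
    "#fdbf6f", "#ff7f00", "#cab2d6", "#6a3d9a", "#ffff99", "#b15928",
)

MENSURAL = "mensural"
MERISTIC = "meristic"


@dataclass
class PhenotypeMatrix:
    """Taxon labels plus numeric trait columns with per-trait kind.

    Parameters
    ----------
    taxa : pd.Series
        Taxon/population label per individual (index = individual ids).
    traits : pd.DataFrame
        Numeric trait columns aligned with ``taxa``.  NaN marks an absent
        observation (e.g. after trait-wise outlier removal).
    trait_kind : dict
        Trait name -> ``"mensural"`` or ``"meristic"``.
    """

    taxa: pd.Series
    traits: pd.DataFrame
    trait_kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxa = pd.Series(self.taxa).astype(str)
        self.traits = pd.DataFrame(self.traits)
        if len(self.taxa) != len(self.traits):
            raise PhenotypeError(
                f"taxa ({len(self.taxa)}) and traits ({len(self.traits)}) differ in length"
            )
        self.traits.index = self.taxa.index
        for col in self.traits.columns:
            if not pd.api.types.is_numeric_dtype(self.traits[col]):
                raise PhenotypeError(f"trait column {col!r} is not numeric")
        if not self.trait_kind:
            self.trait_kind = {c: classify_trait(self.traits[c]) for c in self.traits.columns}
        missing = set(self.traits.columns) - set(self.trait_kind)
        extra = set(self.trait_kind) - set(self.traits.columns)
        if missing or extra:
            raise PhenotypeError(
                f"trait_kind mismatch: missing={sorted(missing)}, extra={sorted(extra)}"
            )

    # ------------------------------------------------------------------
    @property
    def taxon_levels(self) -> list[str]:
        """Unique taxon labels, sorted lexicographically."""
        return sorted(self.taxa.unique())

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.taxa)

    def mensural_traits(self) -> list[str]:
        return [t for t in self.trait_names if self.trait_kind[t] == MENSURAL]

    def meristic_traits(self) -> list[str]:
        return [t for t in self.trait_names if self.trait_kind[t] == MERISTIC]

    def group_values(self, trait: str, taxon: str) -> np.ndarray:
        """Non-missing values of ``trait`` for individuals of ``taxon``."""
        v = self.traits.loc[self.taxa == taxon, trait]
        return v.dropna().to_numpy(dtype=float)

    def sorted_by_taxon(self) -> "PhenotypeMatrix":
        """Rows reordered by taxon label (stable within taxon)."""
        order = self.taxa.sort_values(kind="stable").index
        return PhenotypeMatrix(
            self.taxa.loc[order], self.traits.loc[order], dict(self.trait_kind)
        )

    def copy(self) -> "PhenotypeMatrix":
        return PhenotypeMatrix(self.taxa.copy(), self.traits.copy(), dict(self.trait_kind))

    def to_frame(self, species_column: str = "species") -> pd.DataFrame:
        out = self.traits.copy()
        out.insert(0, species_column, self.taxa)
        return out

    def to_csv(self, path: str | Path, species_column: str = "species") -> None:
        self.to_frame(species_column).to_csv(path, index=False)

    def complete_cases(self) -> "PhenotypeMatrix":
        """Rows with every trait observed (required by distance/LDA stages)."""
        keep = self.traits.notna().all(axis=1)
        return PhenotypeMatrix(self.taxa[keep], self.traits[keep], dict(self.trait_kind))


def classify_trait(values: Iterable[float], override: str | None = None) -> str:
    """Classify a trait as meristic (all integer-valued) or mensural.

    The rule is a heuristic — counts are integers, measurements almost
    never are — and an explicit ``override`` always wins.  Misclassification
    only changes plot style (box-only vs violin), never the statistics.
    """
    if override is not None:
        if override not in (MENSURAL, MERISTIC):
            raise PhenotypeError(f"unknown trait kind override {override!r}")
        return override
    v = pd.Series(list(values), dtype=float).dropna().to_numpy()
    if v.size == 0:
        raise PhenotypeError("cannot classify an all-missing trait")
    return MERISTIC if np.allclose(v, np.round(v)) else MENSURAL


def read_phenotype_csv(
    path: str | Path,
    species_column: str = "species",
    drop_columns: Sequence[str] = (),
    trait_kind_override: Mapping[str, str] | None = None,
) -> PhenotypeMatrix:
    """Read a species-by-trait CSV into a :class:`PhenotypeMatrix`.

    The file must carry a header row; one column (default ``species``,
    matched case-insensitively) holds taxon labels and every remaining
    column after ``drop_columns`` removal must be numeric.  Rows are sorted
    alphabetically by taxon so all downstream output is input-order
    invariant.
    """
    path = Path(path)
    if not path.exists():
        raise PhenotypeError(f"input file not found: {path}")
    df = pd.read_csv(path)
    col_lookup = {c.lower(): c for c in df.columns}
    key = species_column.lower()
    if key not in col_lookup:
        raise PhenotypeError(
            f"species column {species_column!r} not found (columns: {list(df.columns)})"
        )
    species_column = col_lookup[key]
    df = df.drop(columns=[c for c in drop_columns if c in df.columns])

    taxa = df[species_column].astype(str)
    trait_df = df.drop(columns=[species_column])
    if trait_df.shape[1] == 0:
        raise PhenotypeError("no trait columns in input")
    for col in trait_df.columns:
        coerced = pd.to_numeric(trait_df[col], errors="coerce")
        bad = coerced.isna() & trait_df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise PhenotypeError(
                f"non-numeric value {trait_df[col][row]!r} in trait column "
                f"{col!r} at row {row}"
            )
        trait_df[col] = coerced
    if taxa.nunique() < 2:
        raise PhenotypeError("need at least 2 distinct taxa")

    override = dict(trait_kind_override or {})
    kinds = {
        c: classify_trait(trait_df[c], override.get(c)) for c in trait_df.columns
    }
    return PhenotypeMatrix(taxa, trait_df, kinds).sorted_by_taxon()


def assign_colors(
    taxon_levels: Sequence[str], palette: Sequence[str] = DEFAULT_PALETTE
) -> dict[str, str]:
    """Deterministic taxon -> colour map, cycling when taxa outnumber colours."""
    if len(palette) == 0:
        raise PhenotypeError("palette must contain at least one colour")
    return {t: palette[i % len(palette)] for i, t in enumerate(taxon_levels)}
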