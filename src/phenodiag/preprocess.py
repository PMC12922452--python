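"""Optional preprocessing: allometric size correction and audited outlier removal.

Allometric correction replaces each mensural trait y by the residuals of
the ordinary least-squares fit ln(y) = a + b·ln(size), where *size* is a
user-chosen scaling proxy (snout–vent length, stem height, ...).  The
residuals are size-independent shape variables; meristic traits pass
through untouched and the scaling trait itself leaves the trait set.

Outlier removal applies Tukey's IQR fences per taxon and per trait: a value
is flagged iff it falls strictly below Q1 − k·IQR or strictly above
Q3 + k·IQR computed within its own taxon, so genuine between-species
differences are never mistaken for aberrant values.  Flagged cells become
missing for that trait only, and every removal is logged (taxon, trait,
value, fences) so the filtering is fully auditable.

Both steps are exposed as sklearn-style transformers
(:class:`AllometricCorrector`, :class:`TukeyOutlierFilter`) and as plain
functions (:func:`allometric_correct`, :func:`remove_outliers`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core_data import MENSURAL, PhenotypeError, PhenotypeMatrix

__all__ = [
    "AllometryResult",
    "RemovalLog",
    "AllometricCorrector",
    "TukeyOutlierFilter",
    "allometric_correct",
    "tukey_fences",
    "remove_outliers",
]


# ----------------------------------------------------------------------
# Allometric correction
# ----------------------------------------------------------------------

@dataclass
class AllometryResult:
    """Adjusted matrix plus the per-trait log–log regressions behind it."""

    adjusted: PhenotypeMatrix
    scaling_trait: str
    regressions: dict[str, tuple[float, float, int]]  # trait -> (slope, intercept, n)


class AllometricCorrector(BaseEstimator, TransformerMixin):
    """Replace mensural traits by residuals of ln(trait) ~ ln(scaling_trait).

    Parameters
    ----------
    scaling_trait : str
        Name of the mensural size proxy; must be strictly positive.
    fit_scope : {"pooled", "per_taxon"}
        ``pooled`` (default) fits one common line per trait across all
        individuals; ``per_taxon`` fits a separate line within each taxon.

    Attributes
    ----------
    regressions_ : dict
        trait -> (slope, intercept, n) for pooled fits; with
        ``fit_scope="per_taxon"`` the values are dicts taxon -> (slope,
        intercept, n).
    """

    def __init__(self, scaling_trait: str = "", fit_scope: str = "pooled"):
        self.scaling_trait = scaling_trait
        self.fit_scope = fit_scope

    # -- helpers -------------------------------------------------------
    def _validate(self, m: PhenotypeMatrix) -> list[str]:
        if self.fit_scope not in ("pooled", "per_taxon"):
            raise PhenotypeError(f"unknown fit_scope {self.fit_scope!r}")
        if self.scaling_trait not in m.trait_names:
            raise PhenotypeError(f"scaling trait {self.scaling_trait!r} not in matrix")
        if m.trait_kind[self.scaling_trait] != MENSURAL:
            raise PhenotypeError(
                f"scaling trait {self.scaling_trait!r} is meristic; need a mensural size proxy"
            )
        targets = [t for t in m.mensural_traits() if t != self.scaling_trait]
        for t in targets + [self.scaling_trait]:
            vals = m.traits[t].dropna()
            if (vals <= 0).any():
                taxon = m.taxa[(m.traits[t] <= 0)].iloc[0]
                raise PhenotypeError(
                    f"non-positive value in trait {t!r} (taxon {taxon!r}); "
                    "log transform requires strictly positive measurements"
                )
        return targets

    @staticmethod
    def _ols(lx: np.ndarray, ly: np.ndarray, trait: str) -> tuple[float, float, int]:
        n = lx.size
        if n < 3:
            raise PhenotypeError(
                f"trait {trait!r}: only {n} complete pairs; need >=3 for a regression"
            )
        slope, intercept = np.polyfit(lx, ly, 1)
        return float(slope), float(intercept), int(n)

    # -- sklearn API ---------------------------------------------------
    def fit(self, m: PhenotypeMatrix, y=None) -> "AllometricCorrector":
        targets = self._validate(m)
        lsize = np.log(m.traits[self.scaling_trait].to_numpy(dtype=float))
        self.regressions_: dict = {}
        for t in targets:
            ly = np.log(m.traits[t].to_numpy(dtype=float))
            ok = np.isfinite(lsize) & np.isfinite(ly)
            if self.fit_scope == "pooled":
                self.regressions_[t] = self._ols(lsize[ok], ly[ok], t)
            else:
                per = {}
                for taxon in m.taxon_levels:
                    sel = ok & (m.taxa == taxon).to_numpy()
                    per[taxon] = self._ols(lsize[sel], ly[sel], f"{t}[{taxon}]")
                self.regressions_[t] = per
        self.targets_ = targets
        return self

    def transform(self, m: PhenotypeMatrix) -> PhenotypeMatrix:
        self._validate(m)
        lsize = np.log(m.traits[self.scaling_trait].to_numpy(dtype=float))
        traits = m.traits.copy()
        for t in self.targets_:
            ly = np.log(traits[t].to_numpy(dtype=float))
            resid = np.full_like(ly, np.nan)
            ok = np.isfinite(lsize) & np.isfinite(ly)
            if self.fit_scope == "pooled":
                slope, intercept, _ = self.regressions_[t]
                resid[ok] = ly[ok] - (intercept + slope * lsize[ok])
            else:
                for taxon, (slope, intercept, _) in self.regressions_[t].items():
                    sel = ok & (m.taxa == taxon).to_numpy()
                    resid[sel] = ly[sel] - (intercept + slope * lsize[sel])
            traits[t] = resid
        traits = traits.drop(columns=[self.scaling_trait])
        kinds = {k: v for k, v in m.trait_kind.items() if k != self.scaling_trait}
        return PhenotypeMatrix(m.taxa.copy(), traits, kinds)


def allometric_correct(
    m: PhenotypeMatrix, scaling_trait: str, fit_scope: str = "pooled"
) -> AllometryResult:
    """Fit-and-apply allometric correction; see :class:`AllometricCorrector`."""
    corr = AllometricCorrector(scaling_trait=scaling_trait, fit_scope=fit_scope).fit(m)
    return AllometryResult(corr.transform(m), scaling_trait, corr.regressions_)


# ----------------------------------------------------------------------
# Tukey-fence outlier removal
# ----------------------------------------------------------------------

@dataclass
class RemovalLog:
    """Audit trail of outlier deletions, exportable as CSV."""

    records: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    parameters: tuple[float, float, float] = (0.25, 0.75, 1.5)
    exempt_groups: list[tuple[str, str, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        lq, uq, k = self.parameters
        df = pd.DataFrame(
            self.records,
            columns=["taxon", "trait", "value", "lower_fence", "upper_fence"],
        )
        df["lower_q"], df["upper_q"], df["k"] = lq, uq, k
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)


def tukey_fences(
    values, lower_q: float = 0.25, upper_q: float = 0.75, k: float = 1.5
) -> tuple[float, float]:
    """Tukey-style fences (Q_low − k·IQR, Q_high + k·IQR).

    Quantiles use linear interpolation of order statistics (the common
    "type 7" default).  Values strictly outside the fences are outliers;
    boundary values are retained.
    """
    if not (0 < lower_q < 0.5 < upper_q < 1):
        raise PhenotypeError(f"quantiles must satisfy 0<lower_q<0.5<upper_q<1, got {lower_q},{upper_q}")
    if k <= 0:
        raise PhenotypeError(f"fence multiplier k must be positive, got {k}")
    v = pd.Series(values, dtype=float).dropna().to_numpy()
    if v.size == 0:
        raise PhenotypeError("cannot compute fences on an empty vector")
    q1, q3 = np.quantile(v, [lower_q, upper_q])  # linear interpolation
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


class TukeyOutlierFilter(BaseEstimator, TransformerMixin):
    """Per-taxon, per-trait Tukey-fence outlier removal with audit log.

    Groups with fewer than ``min_group_size`` observed values for a trait
    are exempt from flagging (fences from <=3 points are meaningless); the
    exemption is logged.

    Attributes
    ----------
    fences_ : dict
        (taxon, trait) -> (lower_fence, upper_fence).
    removal_log_ : RemovalLog
        Populated by :meth:`transform`.
    """

    MIN_GROUP_SIZE = 4

    def __init__(self, lower_q: float = 0.25, upper_q: float = 0.75, k: float = 1.5):
        self.lower_q = lower_q
        self.upper_q = upper_q
        self.k = k

    def fit(self, m: PhenotypeMatrix, y=None) -> "TukeyOutlierFilter":
        self.fences_: dict[tuple[str, str], tuple[float, float]] = {}
        self.exempt_: list[tuple[str, str, int]] = []
        for trait in m.trait_names:
            for taxon in m.taxon_levels:
                vals = m.group_values(trait, taxon)
                if vals.size < self.MIN_GROUP_SIZE:
                    self.exempt_.append((taxon, trait, int(vals.size)))
                    continue
                self.fences_[(taxon, trait)] = tukey_fences(
                    vals, self.lower_q, self.upper_q, self.k
                )
        return self

    def transform(self, m: PhenotypeMatrix) -> PhenotypeMatrix:
        log = RemovalLog(parameters=(self.lower_q, self.upper_q, self.k))
        log.exempt_groups = list(self.exempt_)
        traits = m.traits.copy()
        for (taxon, trait), (lo, hi) in self.fences_.items():
            col = traits[trait]
            mask = (m.taxa == taxon) & col.notna() & ((col < lo) | (col > hi))
            for idx in traits.index[mask]:
                log.records.append((taxon, trait, float(col[idx]), lo, hi))
            traits.loc[mask, trait] = np.nan
        self.removal_log_ = log
        # taxon levels / colour maps are recomputed downstream from the new
        # matrix, so rebuilding amounts to constructing a fresh object
        return PhenotypeMatrix(m.taxa.copy(), traits, dict(m.trait_kind))


def remove_outliers(
    m: PhenotypeMatrix,
    lower_q: float = 0.25,
    upper_q: float = 0.75,
    k: float = 1.5,
) -> tuple[PhenotypeMatrix, RemovalLog]:
    """Flag-and-blank outliers per (taxon, trait); returns matrix + audit log."""
    filt = TukeyOutlierFilter(lower_q=lower_q, upper_q=upper_q, k=k).fit(m)
    cleaned = filt.transform(m)
    return cleaned, filt.removal_log_
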