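"""Synthetic phenotype generator with known ground truth.

Emulates the structure the pipeline assumes in real morphometric data:
log-normally distributed body size with per-taxon mean shifts, mensural
traits built as exp(a + b·ln(size) + ε) so that a log–log regression
recovers the planted allometric slope b, Poisson-distributed meristic
counts, optional planted non-overlapping (diagnostic) traits realized by
disjoint supports, planted outliers at fixed SD offsets, and unbalanced
group sizes.  Everything is determined by the spec's seed.

The defaults model a modest species-description study: three taxa with
20–30 individuals each, three mensural traits with slopes between 0.7 and
0.9 around a size proxy, and one meristic count trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import MENSURAL, MERISTIC, PhenotypeError, PhenotypeMatrix
from .preprocess import tukey_fences

__all__ = ["SimSpec", "GroundTruth", "generate", "generate_clusters"]


def _default_mensural() -> dict[str, tuple[float, float, float]]:
    # trait -> (intercept a, allometric slope b, residual sd on log scale)
    return {
        "head_length": (-1.0, 0.90, 0.05),
        "limb_length": (-0.5, 0.80, 0.05),
        "eye_diameter": (-2.0, 0.70, 0.08),
    }


def _default_meristic() -> dict[str, tuple[float, ...]]:
    # trait -> per-taxon Poisson mean
    return {"scale_count": (12.0, 14.0, 16.0)}


@dataclass
class SimSpec:
    """Ground-truth description of a synthetic phenotype dataset."""

    taxa: tuple[str, ...] = ("sp_a", "sp_b", "sp_c")
    n_per_taxon: tuple[int, ...] = (30, 25, 20)  # unbalanced by default
    size_trait: str = "body_size"
    size_log_mean: tuple[float, ...] = (3.80, 4.10, 4.40)  # per-taxon ln-mean
    size_log_sd: float = 0.30  # ~30% CV: a pooled sample spanning ontogeny
    mensural: dict[str, tuple[float, float, float]] = field(default_factory=_default_mensural)
    meristic: dict[str, tuple[float, ...]] = field(default_factory=_default_meristic)
    #: (trait, (taxon_a, taxon_b), gap) — ranges made disjoint with this gap
    planted_nonoverlap: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    #: (taxon, trait, offset in group-SD units, count)
    planted_outliers: list[tuple[str, str, float, int]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if len(self.taxa) != len(self.n_per_taxon):
            raise PhenotypeError("taxa and n_per_taxon lengths differ")
        if len(self.size_log_mean) != len(self.taxa):
            raise PhenotypeError("size_log_mean must give one value per taxon")
        for name, (_, _, sd) in self.mensural.items():
            if sd <= 0:
                raise PhenotypeError(f"mensural trait {name!r}: residual sd must be > 0")
        for name, means in self.meristic.items():
            if len(means) != len(self.taxa) or any(m < 0 for m in means):
                raise PhenotypeError(f"meristic trait {name!r}: need one mean >= 0 per taxon")
        for trait, (a, b), gap in self.planted_nonoverlap:
            if gap <= 0:
                raise PhenotypeError(f"planted non-overlap {trait!r} ({a},{b}): gap must be > 0")
            if a not in self.taxa or b not in self.taxa or a == b:
                raise PhenotypeError(f"planted non-overlap {trait!r}: bad taxon pair ({a},{b})")
        for taxon, trait, _, count in self.planted_outliers:
            if taxon not in self.taxa or count < 0:
                raise PhenotypeError(f"planted outlier spec invalid: {taxon},{trait}")


@dataclass
class GroundTruth:
    spec: SimSpec
    slopes: dict[str, float]
    outliers: pd.DataFrame        # taxon, trait, row_id, value
    nonoverlap: pd.DataFrame      # trait, taxon_a, taxon_b, gap

    def to_csv(self, path: str | Path) -> None:
        """Sidecar ground-truth export (outliers table)."""
        self.outliers.to_csv(path, index=False)


def generate(spec: SimSpec) -> tuple[PhenotypeMatrix, GroundTruth]:
    """Draw a phenotype matrix from the spec; fully determined by its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    taxa_col, cols = [], {}
    for taxon, n in zip(spec.taxa, spec.n_per_taxon):
        taxa_col.extend([taxon] * n)
    taxa_col = pd.Series(taxa_col, name="species")
    n_total = len(taxa_col)

    ln_size = np.concatenate([
        rng.normal(mu, spec.size_log_sd, n)
        for mu, n in zip(spec.size_log_mean, spec.n_per_taxon)
    ])
    cols[spec.size_trait] = np.exp(ln_size)

    slopes = {}
    for trait, (a, b, sd) in spec.mensural.items():
        eps = rng.normal(0.0, sd, n_total)
        cols[trait] = np.exp(a + b * ln_size + eps)
        slopes[trait] = b

    for trait, means in spec.meristic.items():
        cols[trait] = np.concatenate([
            rng.poisson(mu, n).astype(float)
            for mu, n in zip(means, spec.n_per_taxon)
        ])

    # planted diagnostic traits: the named pair gets disjoint supports,
    # every other taxon spans both so only that pair is non-overlapping
    no_rows = []
    for trait, (ta, tb), gap in spec.planted_nonoverlap:
        v = np.empty(n_total)
        for taxon, n in zip(spec.taxa, spec.n_per_taxon):
            mask = (taxa_col == taxon).to_numpy()
            if taxon == ta:
                v[mask] = rng.uniform(0.0, 1.0, mask.sum())
            elif taxon == tb:
                v[mask] = rng.uniform(1.0 + gap, 2.0 + gap, mask.sum())
            else:
                v[mask] = rng.uniform(0.5, 1.5 + gap, mask.sum())
        cols[trait] = v
        no_rows.append({"trait": trait, "taxon_a": min(ta, tb),
                        "taxon_b": max(ta, tb), "gap": gap})

    traits = pd.DataFrame(cols)
    kinds = {spec.size_trait: MENSURAL}
    kinds.update({t: MENSURAL for t in spec.mensural})
    kinds.update({t: MERISTIC for t in spec.meristic})
    kinds.update({t: MENSURAL for t, _, _ in spec.planted_nonoverlap})

    out_rows = []
    for taxon, trait, offset_sd, count in spec.planted_outliers:
        mask = (taxa_col == taxon).to_numpy()
        idx = rng.choice(np.flatnonzero(mask), size=count, replace=False)
        clean = traits.loc[mask, trait].to_numpy()
        mu, sd = clean.mean(), clean.std(ddof=1)
        # outliers planted above the mean: mensural traits live on a strictly
        # positive scale, so low-side 10-sigma values would be unmeasurable
        planted = mu + offset_sd * sd * (1.0 + 0.05 * rng.random(count))
        if kinds.get(trait) == MERISTIC:
            planted = np.round(planted)  # keep count traits integer-valued
        traits.loc[idx, trait] = planted
        for i, v in zip(idx, planted):
            out_rows.append({"taxon": taxon, "trait": trait, "row_id": int(i),
                             "value": float(v)})
        # the generator guarantees planted points are flaggable at defaults
        lo, hi = tukey_fences(traits.loc[mask, trait])
        if not np.all((planted < lo) | (planted > hi)):
            raise PhenotypeError(
                f"planted outliers for ({taxon},{trait}) fall inside Tukey fences; "
                "increase offset_sd"
            )

    pm = PhenotypeMatrix(taxa_col, traits, kinds).sorted_by_taxon()
    gt = GroundTruth(
        spec=spec,
        slopes=slopes,
        outliers=pd.DataFrame(out_rows, columns=["taxon", "trait", "row_id", "value"]),
        nonoverlap=pd.DataFrame(no_rows, columns=["trait", "taxon_a", "taxon_b", "gap"]),
    )
    return pm, gt


def generate_clusters(
    n_taxa: int = 3,
    n_per_taxon: int = 20,
    n_traits: int = 4,
    separation: float = 0.0,
    sd: float = 1.0,
    seed: int = 0,
) -> PhenotypeMatrix:
    """Plain Gaussian clusters (no allometry) for multivariate tests.

    Taxon k's mean is shifted by ``separation * sd`` along every trait in a
    simplex-like pattern (taxon index added to alternating coordinates), so
    ``separation=0`` gives exchangeable groups and large values give
    well-separated spherical clusters.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k in range(n_taxa):
        mean = np.zeros(n_traits)
        mean[k % n_traits] += k * separation * sd
        mean[(k + 1) % n_traits] += k * separation * sd * 0.5
        rows.append(rng.normal(mean, sd, size=(n_per_taxon, n_traits)))
        labels.extend([f"taxon_{chr(97 + k)}"] * n_per_taxon)
    X = np.vstack(rows)
    traits = pd.DataFrame(X, columns=[f"trait_{i+1}" for i in range(n_traits)])
    kinds = {c: MENSURAL for c in traits.columns}
    return PhenotypeMatrix(pd.Series(labels, name="species"), traits, kinds)
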