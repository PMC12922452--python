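"""Bundled validation inputs.

Two small reference objects used throughout the tests and the
reproduction script:

* the canonical three-species iris flower measurements (150 individuals,
  4 mensural traits), loaded from scikit-learn's bundled copy and exposed
  as a :class:`~phenodiag.core_data.PhenotypeMatrix`;
* a published jackknife cross-classification table for nine Caribbean
  *Anolis* species (80 individuals), transcribed from the original report,
  used to validate the confusion-matrix-derived diagnostics (sensitivity,
  specificity, TSS, accuracy) against printed values.
"""

from __future__ import annotations

import pandas as pd
from sklearn.datasets import load_iris

from .core_data import PhenotypeMatrix
from .multivariate import ConfusionMatrix

__all__ = ["iris_phenotypes", "anole_reference_confusion"]


def iris_phenotypes() -> PhenotypeMatrix:
    """Iris measurements as a phenotype matrix (all traits mensural)."""
    bunch = load_iris(as_frame=True)
    traits = bunch.frame.drop(columns="target")
    traits.columns = [
        c.replace(" (cm)", "").replace(" ", "_") for c in traits.columns
    ]
    taxa = bunch.target.map(dict(enumerate(bunch.target_names))).astype(str)
    taxa.name = "species"
    # measurements recorded to 0.1 cm are integer-valued in mm; force mensural
    kinds = {c: "mensural" for c in traits.columns}
    return PhenotypeMatrix(taxa, traits, kinds).sorted_by_taxon()


# Jackknife cross-classification of nine anole species (rows = a priori
# class, columns = predicted class); 57 of 80 on the diagonal (71.25%).
_ANOLE_CLASSES = ["alli", "bru", "car", "fai", "lon", "may", "por", "sma", "tor"]
_ANOLE_COUNTS = [
    [9, 1, 0, 0, 0, 0, 0, 0, 0],
    [0, 8, 0, 1, 0, 0, 1, 0, 0],
    [0, 0, 9, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 4, 0, 0, 0, 1, 1],
    [0, 0, 0, 0, 10, 0, 0, 0, 0],
    [0, 0, 1, 0, 0, 2, 0, 0, 0],
    [0, 0, 0, 0, 0, 2, 6, 2, 2],
    [0, 0, 0, 1, 0, 0, 2, 6, 1],
    [0, 1, 0, 0, 0, 0, 3, 0, 6],
]


def anole_reference_confusion() -> ConfusionMatrix:
    """Published nine-species anole jackknife confusion matrix."""
    counts = pd.DataFrame(_ANOLE_COUNTS, index=_ANOLE_CLASSES,
                          columns=_ANOLE_CLASSES, dtype=int)
    return ConfusionMatrix(counts)
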