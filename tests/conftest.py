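import numpy as np
import pandas as pd
import pytest

from phenodiag.core_data import PhenotypeMatrix
from phenodiag.datasets import iris_phenotypes


def make_matrix(taxa, **trait_columns) -> PhenotypeMatrix:
    """Build a small PhenotypeMatrix from per-trait value lists."""
    return PhenotypeMatrix(pd.Series(list(taxa)), pd.DataFrame(trait_columns))


@pytest.fixture(scope="session")
def iris() -> PhenotypeMatrix:
    return iris_phenotypes()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
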