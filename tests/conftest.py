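import numpy as np
import pandas as pd
import pytest

from evimpute.matrix_io import AbundanceMatrix, SampleDesign
from evimpute.simulate import SyntheticSpec, generate_matrix, worked_example_matrix


@pytest.fixture
def design3() -> SampleDesign:
    return SampleDesign.from_populations({"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]})


@pytest.fixture
def worked_example() -> AbundanceMatrix:
    return worked_example_matrix()


def make_matrix(rows, design, ids=None) -> AbundanceMatrix:
    """Build a matrix from a list of row value lists."""
    ids = ids or [f"P{i}" for i in range(len(rows))]
    df = pd.DataFrame(rows, index=pd.Index(ids, name="protein"), columns=list(design.sample_ids))
    return AbundanceMatrix(df.astype(float), design)


@pytest.fixture
def synthetic_standard():
    """The standard correlated synthetic matrix used across suites."""
    return generate_matrix(
        SyntheticSpec(
            n_complete=80, n_imputable=50, n_one_pop=30, n_excluded=15,
            noise_sigma=0.2, seed=11, n_differential=8,
        )
    )
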