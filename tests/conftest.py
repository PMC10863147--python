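import numpy as np
import pandas as pd
import pytest

from drivergene import ExpressionMatrix, GeneSetCollection


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 genes x 4 samples of raw counts."""
    df = pd.DataFrame(
        [[10, 20, 30, 40], [5, 0, 15, 20], [100, 200, 300, 400]],
        index=["TP53", "PRNP", "GAPDH"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df, layer="counts")


@pytest.fixture
def gene_sets() -> GeneSetCollection:
    return GeneSetCollection.from_dict(
        {"SET_A": ["TP53", "PRNP"], "SET_B": ["GAPDH", "PRNP"], "SET_C": ["TP53", "GAPDH", "PRNP"]}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
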