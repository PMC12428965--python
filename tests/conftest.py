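import numpy as np
import pandas as pd
import pytest

from translatome.io import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_counts(values, genes=None, samples=None, fraction="mixed"):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(
        pd.DataFrame(values.astype(np.int64), index=genes, columns=samples),
        fraction=fraction,
    )


def make_sheet(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "condition",
            "fraction",
            "biological_replicate",
            "technical_replicate",
        ],
    )


@pytest.fixture
def counts_factory():
    return make_counts


@pytest.fixture
def sheet_factory():
    return make_sheet
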