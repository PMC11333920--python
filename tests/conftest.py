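import numpy as np
import pandas as pd
import pytest

from phyllonet.tables import CountTable


def make_count_table(counts, compartment=None, timepoint=None, taxonomy=None):
    """CountTable from a dict/array with minimal metadata."""
    df = pd.DataFrame(counts)
    df.index = [f"Otu{i + 1}" for i in range(df.shape[0])] if df.index.dtype != object else df.index
    n = df.shape[1]
    df.columns = [f"s{i + 1}" for i in range(n)] if df.columns.dtype != object else df.columns
    md = pd.DataFrame(
        {
            "compartment": compartment or ["epiphyte"] * n,
            "site": ["site1"] * n,
            "season": ["spring"] * n,
            "year": [2014] * n,
            "timepoint": timepoint or [0] * n,
        },
        index=df.columns,
    )
    tax = pd.Series(taxonomy, index=df.index) if taxonomy is not None else None
    return CountTable(df, md, taxonomy=tax)


@pytest.fixture
def toy_table():
    return make_count_table(np.array([[5, 0, 7], [2, 3, 1], [0, 60, 9]]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
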