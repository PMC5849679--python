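import numpy as np
import pandas as pd
import pytest

from phosbench import IntensityTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """2 features x 3 samples, one condition pair with replicates."""
    values = pd.DataFrame(
        [[8.0, 2.0, 4.0], [1.0, 2.0, np.nan]],
        index=["f1", "f2"],
        columns=["s1", "s2", "s3"],
    )
    sample_meta = pd.DataFrame(
        {
            "condition": ["dox", "ctrl", "dox"],
            "replicate": [1, 1, 2],
        },
        index=values.columns,
    )
    feature_meta = pd.DataFrame(
        {"species": ["human", "yeast"], "localization_prob": [0.9, 0.5]},
        index=values.index,
    )
    return IntensityTable(values, feature_meta, sample_meta)


def make_table(values, conditions=None, replicates=None, **feature_cols):
    """Build an IntensityTable from a plain array with generated ids."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    idx = [f"f{i+1}" for i in range(n)]
    cols = [f"s{j+1}" for j in range(m)]
    fmeta = pd.DataFrame(feature_cols, index=idx) if feature_cols else None
    smeta = pd.DataFrame(index=pd.Index(cols))
    if conditions is not None:
        smeta["condition"] = conditions
    if replicates is not None:
        smeta["replicate"] = replicates
    return IntensityTable(
        pd.DataFrame(values, index=idx, columns=cols),
        fmeta,
        smeta if len(smeta.columns) else None,
    )
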