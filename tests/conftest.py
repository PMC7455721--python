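import numpy as np
import pandas as pd
import pytest

from deadstab.io import CountMatrix


@pytest.fixture
def two_group_series():
    return pd.Series(
        {
            "ctrl_1": "control",
            "ctrl_2": "control",
            "ctrl_3": "control",
            "ko_1": "knockout",
            "ko_2": "knockout",
            "ko_3": "knockout",
        }
    )


@pytest.fixture
def small_counts(two_group_series):
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(200, size=(20, 6)),
        index=[f"g{i}" for i in range(20)],
        columns=two_group_series.index,
    )
    return CountMatrix(counts, two_group_series, "exon")
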