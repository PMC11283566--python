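import numpy as np
import pandas as pd
import pytest

from rhizoactive import CountTable, pair_assays


@pytest.fixture
def toy_counts() -> CountTable:
    return CountTable(pd.DataFrame(
        [[5, 0, 3], [2, 7, 0], [1, 1, 1]],
        index=["s1", "s2", "s3"], columns=["ta", "tb", "tc"],
    ))


@pytest.fixture
def toy_metadata() -> pd.DataFrame:
    rows = []
    for i, (drought, day) in enumerate(
        [("pre-drought", 0), ("drought", 2), ("watered", 2)], start=1
    ):
        rows.append({
            "sample_id": f"s{i}", "crop": "bean", "planted": "planted",
            "drought": drought, "day": day, "replicate": 1,
            "is_negative_control": False, "dna_concentration": 10.0,
        })
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def toy_assay():
    dna = CountTable(pd.DataFrame(
        [[3, 5, 0, 6], [2, 4, 0, 1], [1, 3, 0, 0]],
        index=["s1", "s2", "s3"], columns=list("abcd"),
    ))
    cdna = CountTable(pd.DataFrame(
        [[3, 2, 4, 0], [4, 1, 5, 0], [2, 0, 0, 1]],
        index=["s1", "s2", "s3"], columns=list("abcd"),
    ))
    return pair_assays(dna, cdna)


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
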