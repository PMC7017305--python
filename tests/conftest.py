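import numpy as np
import pandas as pd
import pytest

from splicenet.preprocess import ExpressionMatrix


@pytest.fixture
def toy_2x2_matrix():
    """One gene, balanced 2x2 design with 2 replicates: cells {1,2},{3,4},{5,6},{7,8}."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]],
        index=["g1"],
        columns=[f"s{i}" for i in range(8)],
    )
    metadata = pd.DataFrame(
        {
            "tissue": ["t1"] * 4 + ["t2"] * 4,
            "state": ["a", "a", "b", "b"] * 2,
        },
        index=values.columns,
    )
    return values, metadata


@pytest.fixture
def unbalanced_2x3():
    """Random unbalanced 2x3 data matching the cohort group sizes."""
    rng = np.random.default_rng(7)
    sizes = {("t1", "a"): 18, ("t1", "b"): 13, ("t1", "c"): 10,
             ("t2", "a"): 17, ("t2", "b"): 13, ("t2", "c"): 10}
    cols, tissue, state = [], [], []
    for (t, s), n in sizes.items():
        for i in range(n):
            cols.append(f"{t}_{s}_{i}")
            tissue.append(t)
            state.append(s)
    values = pd.DataFrame(rng.normal(size=(6, len(cols))),
                          index=[f"g{i}" for i in range(6)], columns=cols)
    metadata = pd.DataFrame({"tissue": tissue, "state": state}, index=cols)
    return values, metadata


@pytest.fixture
def normalized_probe_matrix():
    def make(rows, probes, samples=("s1", "s2")):
        frame = pd.DataFrame(rows, index=probes, columns=list(samples))
        return ExpressionMatrix(frame, level="probe", stage="normalized")

    return make
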