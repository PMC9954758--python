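import numpy as np
import pandas as pd
import pytest

from mfim import CohortTable


@pytest.fixture
def rng():
    return np.random.default_rng(20230214)


@pytest.fixture
def small_table():
    """Five children, six measures, one missing cell."""
    df = pd.DataFrame(
        {
            "iq": [0.5, -1.2, 0.0, 1.1, -0.3],
            "memory": [0.2, -0.8, np.nan, 0.9, -1.5],
            "ran_speed": [-0.1, -2.0, 0.4, 0.7, -0.6],
            "text_accuracy": [-2.1, -2.5, -1.0, 0.1, -2.2],
            "word_accuracy": [-1.8, -2.2, -0.7, 0.3, -2.6],
            "nonword_accuracy": [-2.4, -2.7, -1.3, -0.2, -2.0],
        },
        index=pd.Index([f"c{i}" for i in range(5)], name="child_id"),
    )
    return CohortTable(df)


@pytest.fixture
def correlated_table(rng):
    """60 fully observed children with positively correlated measures."""
    k = 5
    r = np.full((k, k), 0.4)
    np.fill_diagonal(r, 1.0)
    z = rng.standard_normal((60, k)) @ np.linalg.cholesky(r).T
    cols = ["iq", "phonological_awareness", "ran_speed", "visual_search_speed", "memory"]
    df = pd.DataFrame(z, columns=cols,
                      index=pd.Index([f"c{i:03d}" for i in range(60)], name="child_id"))
    signal = z @ np.array([0.25, 0.35, 0.3, 0.2, 0.2])
    df["reading_accuracy"] = signal + 0.5 * rng.standard_normal(60)
    df["reading_speed"] = signal + 0.5 * rng.standard_normal(60)
    return CohortTable(df)
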