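import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def frame(values, rows="r", cols="c") -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{rows}{i}" for i in range(values.shape[0])],
        columns=[f"{cols}{j}" for j in range(values.shape[1])],
    )
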