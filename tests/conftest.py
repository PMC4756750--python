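import numpy as np
import pandas as pd
import pytest

from morphodelim.containers import MeasurementMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_measurements(values, ids=None, labels=None, columns=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    df = pd.DataFrame(
        values,
        index=ids or [f"s{i}" for i in range(n)],
        columns=columns or [f"v{j}" for j in range(p)],
    )
    return MeasurementMatrix(df, labels)


@pytest.fixture
def two_group_matrix(rng):
    """Two well-separated Gaussian groups, complete data."""
    a = rng.multivariate_normal([10, 20, 30], np.eye(3), size=12)
    b = rng.multivariate_normal([16, 26, 36], np.eye(3), size=12)
    m = make_measurements(np.vstack([a, b]),
                          labels=["A"] * 12 + ["B"] * 12)
    truth = {s: (0 if i < 12 else 1) for i, s in enumerate(m.specimen_ids)}
    return m, truth
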