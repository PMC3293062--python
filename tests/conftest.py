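import numpy as np
import pytest

from histotex.image import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_gray8(rng):
    """A random 16x16, 8-level image — small enough for brute-force oracles."""
    return GrayImage(rng.integers(0, 8, size=(16, 16)), levels=16)


@pytest.fixture
def checkerboard16():
    base = np.indices((16, 16)).sum(axis=0) % 2
    return GrayImage(base * 15, levels=16)


@pytest.fixture
def two_blob_table(rng):
    """A toy feature table: two well-separated 2-D Gaussian blobs."""
    import pandas as pd

    a = rng.normal((0.0, 0.0), 0.5, size=(20, 2))
    b = rng.normal((10.0, 10.0), 0.5, size=(20, 2))
    X = np.vstack([a, b])
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(40)],
            "group": ["A"] * 20 + ["B"] * 20,
            "f1": X[:, 0],
            "f2": X[:, 1],
        }
    )
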