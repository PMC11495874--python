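import numpy as np
import pytest

from mvhknn.data import FeatureDataset
from mvhknn.synthetic import BlobConfig, generate_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_blobs():
    """Well-separated two-class blobs, small enough for fast fits."""
    return generate_blobs(BlobConfig(n_per_class=30, d=20, separation=6.0, seed=3))


@pytest.fixture
def tiny_dataset(rng):
    """12 + 12 labelled points in d=8, mildly separated."""
    X0 = rng.standard_normal((12, 8))
    X1 = rng.standard_normal((12, 8)) + 1.5
    return FeatureDataset(
        ids=[f"t{i}" for i in range(24)],
        X=np.vstack([X0, X1]),
        y=np.array([0] * 12 + [1] * 12),
    )
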