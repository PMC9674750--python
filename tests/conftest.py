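import numpy as np
import pytest

from crossmap import ImageInventory, VectorSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_space(rng):
    """30 labeled random vectors in 6 dimensions."""
    labels = [f"word{i:02d}" for i in range(30)]
    return VectorSpace(labels, rng.standard_normal((30, 6)))


@pytest.fixture
def toy_inventory(rng):
    """3 labels x 4 images each, 5-dim features, with frequencies."""
    ids, labels = [], []
    for lab in ("apple", "boat", "cat"):
        for j in range(4):
            ids.append(f"{lab}_{j}")
            labels.append(lab)
    mat = rng.standard_normal((12, 5))
    freq = {"apple": 120.0, "boat": 45.0, "cat": 800.0}
    return ImageInventory(ids, labels, mat, freq)
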