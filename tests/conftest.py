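import numpy as np
import pytest

from urisedclass import FeatureMatrix, ImageRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_records(rng):
    """12 in-memory records, 3 classes, 32x32 random textures."""
    records = []
    for ci, label in enumerate(["alpha", "beta", "gamma"]):
        for i in range(4):
            img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            records.append(ImageRecord(image=img, label=label,
                                       sample_id=f"{label}/{i}.png"))
    return records


def make_feature_matrix(rng, n=30, f=8, n_classes=3, informative=()):
    """Random feature matrix; columns in ``informative`` copy the label."""
    y = rng.integers(0, n_classes, n)
    X = rng.normal(size=(n, f))
    for j in informative:
        X[:, j] = y + 0.01 * rng.normal(size=n)
    return FeatureMatrix(
        values=X,
        sample_ids=[f"s{i:03d}" for i in range(n)],
        labels=[f"c{v}" for v in y],
        feature_names=[f"f{j}" for j in range(f)],
    )


@pytest.fixture
def feature_matrix(rng):
    return make_feature_matrix(rng)
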