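import numpy as np
import pandas as pd
import pytest

from leafcode.synth import ClassConfig, generate_dataset
from leafcode.texture import FEATURE_NAMES


@pytest.fixture(scope="session")
def tiny_configs():
    """Four well-separated classes, small enough to render quickly."""
    return [
        ClassConfig("alpha", 2, 6, (40.0, 10.0, 28.0)),
        ClassConfig("bravo", 2, 6, (60.0, -15.0, 45.0), aspect=1.8),
        ClassConfig("charlie", 1, 6, (30.0, 22.0, 10.0), aspect=2.6),
        ClassConfig("delta", 1, 6, (55.0, 2.0, 15.0), aspect=2.0),
    ]


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_configs):
    """A rendered 4-class dataset: 24 leaves, 48 images, manifest."""
    out = tmp_path_factory.mktemp("tiny_data")
    manifest = generate_dataset(tiny_configs, out_dir=out, seed=11)
    return manifest


def synthetic_feature_frame(
    n_per_class=12, n_classes=3, n_features=8, sep=6.0, seed=0, n_plants=3
):
    """Gaussian-blob feature table shaped like an extraction output
    (one row per image, both surfaces per leaf)."""
    rng = np.random.default_rng(seed)
    rows = []
    names = [f"f{i}" for i in range(n_features)]
    for k in range(n_classes):
        center = rng.normal(0, 1, n_features) + sep * k
        for i in range(n_per_class):
            leaf = f"c{k}_l{i}"
            plant = f"c{k}_p{i % n_plants}"
            base = center + rng.normal(0, 1, n_features)
            for surface in ("adaxial", "abaxial"):
                vals = base + rng.normal(0, 0.1, n_features)
                row = dict(zip(names, vals))
                row.update(
                    leaf_id=leaf, surface=surface, plant_id=plant,
                    folk_type=f"class{k}",
                )
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def blob_features():
    return synthetic_feature_frame()


@pytest.fixture
def feature_names():
    return FEATURE_NAMES
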