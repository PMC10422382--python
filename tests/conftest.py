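import numpy as np
import pytest

from octaco.dataset_io import ImageManifest, ImageRecord, SplitSpec, split_manifest
from octaco.features import FeatureTable
from octaco.fixtures import PlantedTableSpec, SyntheticOCTSpec, make_planted_table, make_synthetic_oct

CLASS_NAMES = ["ARMD", "BRVO", "CRVO", "CSCR", "DME"]


def manifest_with_counts(counts: dict) -> ImageManifest:
    """In-memory manifest with synthetic paths, one record per image."""
    from pathlib import Path

    records = [
        ImageRecord(Path(f"{cls}/{cls.lower()}_{i:04d}.png"), cls)
        for cls in counts
        for i in range(counts[cls])
    ]
    return ImageManifest(records, list(counts))


@pytest.fixture(scope="session")
def planted():
    """Default planted table: 5 classes x 100 samples, 10 informative + 90 noise."""
    table, idx = make_planted_table(PlantedTableSpec(seed=7))
    return table, idx


@pytest.fixture(scope="session")
def tiny_planted():
    """Small planted table for fast unit tests: 3 classes, 8 features."""
    table, idx = make_planted_table(
        PlantedTableSpec(n_per_class=30, n_classes=3, n_informative=3,
                         n_noise=5, class_sep=2.0, seed=3)
    )
    return table, idx


@pytest.fixture(scope="session")
def oct_tree(tmp_path_factory):
    """Small synthetic OCT image tree: 5 classes x 6 images, 96x160 px."""
    root = tmp_path_factory.mktemp("oct")
    spec = SyntheticOCTSpec(
        class_counts={c: 6 for c in CLASS_NAMES}, image_size=(96, 160), seed=11
    )
    return make_synthetic_oct(spec, root)


@pytest.fixture(scope="session")
def oct_manifest(oct_tree):
    from octaco.dataset_io import scan_dataset

    m = scan_dataset(oct_tree)
    return split_manifest(m, SplitSpec(seed=5))


def sign_fixture(n: int = 40, d: int = 4, seed: int = 0) -> FeatureTable:
    """Feature 0 determines the label; remaining columns pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    X[:, 0] = np.where(np.arange(n) % 2 == 0, 3.0, -3.0) + 0.1 * rng.standard_normal(n)
    y = (X[:, 0] > 0).astype(int)
    return FeatureTable(X, y)
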