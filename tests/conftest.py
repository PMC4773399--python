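import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import screenstore as ss

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def store(tmp_path):
    with ss.Store(tmp_path / "screen.db") as st:
        yield st


@pytest.fixture
def small_config():
    """A screen small enough for per-test generation but with every layer
    populated: 96 wells x 2 fields x 2 channels x 3 cells x 4 features."""
    return ss.ScreenConfig(seed=11, n_plates=1, plate_format=96,
                           fields_per_well=2, channels=2, cells_per_image=3,
                           n_features=4)


@pytest.fixture
def small_screen(store, small_config, tmp_path):
    summary = ss.generate(small_config, store, tmp_path / "features.h5")
    return store, summary


def random_long_table(path, rng, n_rows):
    """A seeded random long-layout table plus its in-memory shadow copy."""
    table = ss.FeatureTable.create(path, ss.example_long_schema())
    shadow = {
        "well": rng.integers(0, 20, n_rows),
        "image": rng.integers(0, 50, n_rows),
        "roi": rng.integers(0, 200, n_rows),
        "channel": rng.integers(0, 3, n_rows),
        "feature": rng.integers(0, 5, n_rows),
        "value": rng.normal(size=n_rows),
    }
    table.append_rows(shadow)
    return table, {k: np.asarray(v) for k, v in shadow.items()}
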