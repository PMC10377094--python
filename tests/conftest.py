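import numpy as np
import pytest

from oralfuse import (
    SyntheticFeatureConfig,
    SyntheticImageConfig,
    generate_feature_table,
    generate_image_dataset,
)


@pytest.fixture(scope="session")
def small_image_cfg():
    return SyntheticImageConfig(side_px=96, seed=7)


@pytest.fixture(scope="session")
def small_image_set(small_image_cfg):
    """10 images per class at reduced resolution, shared across tests."""
    return generate_image_dataset(10, small_image_cfg)


@pytest.fixture(scope="session")
def informative_table():
    """400 x 100 table with 10 informative columns at effect size 2."""
    return generate_feature_table(
        SyntheticFeatureConfig(
            n_samples=400, n_features=100, n_informative=10, effect_size=2.0, seed=11
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
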