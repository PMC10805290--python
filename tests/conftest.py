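import numpy as np
import pytest

from repgeom import FeatureMatrix, gen_power_law_features


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_features(rng) -> FeatureMatrix:
    """30 stimuli x 8 channels, anisotropic Gaussian."""
    scales = np.array([4.0, 3.0, 2.0, 1.5, 1.0, 0.7, 0.4, 0.2])
    return FeatureMatrix(rng.standard_normal((30, 8)) * scales)


@pytest.fixture
def powerlaw_features() -> FeatureMatrix:
    return gen_power_law_features(n_stimuli=1000, n_channels=20, alpha=1.0, seed=7)
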