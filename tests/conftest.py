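import numpy as np
import pandas as pd
import pytest

from clinsynth.engine import FeatureSpec, SynthesisConfig


@pytest.fixture
def bivariate_normal():
    """n=2000 bivariate standard normal with Pearson rho = 0.8."""
    rng = np.random.default_rng(10_000)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, 0.8], [0.8, 1.0]], size=2000)
    return pd.DataFrame(z, columns=["x", "y"])


@pytest.fixture
def bivariate_spec():
    return [FeatureSpec("x", "continuous"), FeatureSpec("y", "continuous")]


@pytest.fixture
def default_config():
    return SynthesisConfig(seed=7)
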