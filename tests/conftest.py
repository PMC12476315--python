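import numpy as np
import pytest

from lesionseg.data_model import default_schema
from lesionseg.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_dataset():
    """20 quick 32×32 samples shared by data-model/reporting tests."""
    cfg = GeneratorConfig(image_size=32, n_samples=20, seed=101)
    return cfg, generate_dataset(cfg)


def random_ensemble(rng, T=4, h=6, w=6):
    """Random valid 2-class prediction ensemble."""
    p = rng.uniform(0.02, 0.98, size=(T, h, w))
    return np.stack([p, 1.0 - p], axis=-1)
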