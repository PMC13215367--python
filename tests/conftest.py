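import numpy as np
import pytest

from metseg.network import NetConfig
from metseg.phantom import PhantomConfig


@pytest.fixture
def tiny_net_config():
    """Smallest network reaching the 8^3 bottleneck: 32^3, 2 downsamplings."""
    return NetConfig(input_shape=(32, 32, 32), n_down=2, base_channels=4,
                     vit_layers=2, vit_dim=16, vit_heads=4)


@pytest.fixture
def tiny_phantom_config():
    return PhantomConfig(shape=(32, 32, 32), n_lesions=4, d_max=8.0,
                         noise_sd=5.0, seed=7)


@pytest.fixture
def small_cohort(tmp_path, tiny_phantom_config):
    """A 5-patient phantom cohort on disk; returns (manifest, directory)."""
    from metseg.phantom import generate_cohort
    cohort_dir = tmp_path / "cohort"
    manifest = generate_cohort(tiny_phantom_config, 5, cohort_dir)
    return manifest, cohort_dir


def rng(seed=0):
    return np.random.default_rng(seed)
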