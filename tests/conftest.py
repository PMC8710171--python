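import numpy as np
import pytest

from ganseg.adversarial import DiscriminatorConfig
from ganseg.generator import GeneratorConfig
from ganseg.phantoms import PhantomSpec, generate_phantom
from ganseg.training import TrainConfig, init_state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_configs():
    """Smallest legal model: width-4 generator, narrow discriminator, 32x32."""
    gen_cfg = GeneratorConfig(base_width=4, num_classes=3,
                              block_counts=(1, 1, 1, 1))
    disc_cfg = DiscriminatorConfig(in_channels=2, conv_widths=(4, 4, 8, 8, 8),
                                   fc_width=8, input_size=32)
    return gen_cfg, disc_cfg


@pytest.fixture
def tiny_state(tiny_configs):
    gen_cfg, disc_cfg = tiny_configs
    return init_state(gen_cfg, disc_cfg, TrainConfig(seed=0, epochs=0))


@pytest.fixture(scope="session")
def tiny_batch():
    """Two seeded 32x32 phantoms with labels clipped to 3 classes."""
    spec = PhantomSpec(image_size=32, seed=5)
    imgs = np.stack([generate_phantom(spec, i).image for i in range(2)])
    labs = np.minimum(
        np.stack([generate_phantom(spec, i).label for i in range(2)]), 2)
    return imgs, labs
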