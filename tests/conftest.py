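import numpy as np
import pytest

import segresdeit as sd


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest config exercising every architectural element."""
    return sd.ModelConfig(
        input_size=(32, 32, 3),
        encoder_blocks=((1, 4), (1, 8)),
        bridge_stages=1,
        patch_size=2,
        embed_dim=16,
        depth=1,
        heads=2,
        dropout_rate=0.1,
        variant="segresdeit",
    ).validate()


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = sd.SynthConfig(n_images=8, image_size=(32, 32), lesion_probability=0.75,
                         lesion_radius_range=(5, 8), seed=42)
    return sd.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
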