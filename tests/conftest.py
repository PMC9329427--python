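import numpy as np
import pytest
import sklearn

from sizeaxis import build_encoder, encode, generate_planted_activations, generate_size_stimuli
from sizeaxis.synthetic import PlantedGroundTruth

# skip argument validation inside tight sklearn loops (permutation nulls)
sklearn.set_config(assume_finite=True)


@pytest.fixture(scope="session")
def stimuli48():
    """Default study conditions: 8 ranks x 6 stimuli at 64 px."""
    return generate_size_stimuli(n_ranks=8, n_per_rank=6, image_px=64, seed=11)


@pytest.fixture(scope="session")
def stimuli32():
    """Same design at 32 px for encoder-in-the-loop tests."""
    return generate_size_stimuli(n_ranks=8, n_per_rank=6, image_px=32, seed=11)


@pytest.fixture(scope="session")
def planted_strong(stimuli32):
    """Responses with a strong planted log10 axis (trained-network regime)."""
    truth = PlantedGroundTruth.default(n_channels=64, n_latent=10, seed=21, beta=2.0)
    resp = generate_planted_activations(stimuli32, 64, truth, seed=22)
    return resp, truth


@pytest.fixture(scope="session")
def small_encoder():
    return build_encoder(n_layers=2, channels_per_layer=(8, 16), image_px=32, seed=5)


@pytest.fixture(scope="session")
def encoded32(small_encoder, stimuli32):
    return encode(small_encoder, stimuli32)
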