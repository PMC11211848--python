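"""Shared fixtures: small simulated datasets and tiny trained-size models."""

import numpy as np
import pytest

from lsbucket import seqsim
from lsbucket.lsbnet import InceptionModel, ModelConfig


@pytest.fixture(scope="session")
def small_dataset():
    """n=12 pairs across d in {1..5}, 40 per category."""
    return seqsim.build_dataset(
        n=12, d_range=[1, 2, 3, 4, 5], count_per_category=40, seed=101
    )


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained tiny network (n=12): shape and determinism checks only."""
    cfg = ModelConfig(n=12, l=4, p=2, layers=1, k=3, m=6, channels=8)
    return InceptionModel(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
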