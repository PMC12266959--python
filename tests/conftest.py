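import dataclasses

import numpy as np
import pytest

from scrdan.network import ModelSpec, Network
from scrdan.preprocess import PreprocessConfig, preprocess_pair
from scrdan.simulate import SimulationParams, simulate_pair


@pytest.fixture(scope="session")
def tiny_pair():
    """Small simulated source/target pair (counts layer)."""
    params = SimulationParams(
        n_genes=300, n_source_cells=160, n_target_cells=120, seed=11
    ).with_intensity(0.2)
    return simulate_pair(params)


@pytest.fixture(scope="session")
def tiny_hvg_pair(tiny_pair):
    """Preprocessed (lognorm + HVG) version of the tiny pair."""
    source, target = tiny_pair
    sp, tp, genes = preprocess_pair(
        source, target, PreprocessConfig(n_hvg=100)
    )
    return sp, tp, genes


@pytest.fixture(scope="session")
def tiny_unlabeled_target(tiny_hvg_pair):
    _, tp, _ = tiny_hvg_pair
    return dataclasses.replace(tp, labels=None)


@pytest.fixture()
def small_network():
    """A small seeded network for loss/gradient tests."""
    spec = ModelSpec(
        input_dim=20,
        n_classes=3,
        encoder_dims=(16, 8),
        discriminator_dims=(8,),
        seed=7,
    )
    return Network(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
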