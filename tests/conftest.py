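import numpy as np
import pytest

import trajedit as te


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small noiseless multiplicative world shared by fast tests."""
    world = te.MultiplicativeWorld(
        n_variables=3, n_entities=12, n_steps=12, n_conditions=2, sigma=0.0, seed=7
    )
    return te.simulate_multiplicative(world)


@pytest.fixture(scope="session")
def tiny_scaler(tiny_dataset):
    return te.fit_scaling(tiny_dataset.trajectories)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_scaler):
    """A briefly trained small model (enough to be deterministic + sane)."""
    model = te.ConceptEditor(
        tiny_dataset.trajectories[0].variables, tiny_dataset.table, d_h=16, seed=5
    )
    cfg = te.TrainConfig(max_epochs=5, patience=5, seed=5, batch_size=64)
    model, _ = te.train(model, tiny_dataset.training_triples(3, {1}), tiny_scaler, cfg)
    return model


def identity_scaler(variables, eps=0.01):
    """A ScalingSpec whose working range equals raw units (for algebra tests)."""
    V = len(variables)
    return te.ScalingSpec(list(variables), np.full(V, eps), np.ones(V), eps)
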