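"""Shared fixtures: scaled-down simulated networks and a trained model.

The heavy objects (two 100-neuron simulations and one CNN training run)
are session-scoped so the whole suite pays for them once.  Seeds are
fixed so every run exercises identical data.
"""

import numpy as np
import pytest

from spikeconn import cnn_estimator as cnn
from spikeconn import netsim

TRAIN_SEED = 101
EVAL_SEED = 202
MODEL_SEED = 7
SCALED_N = 100
TRAIN_DURATION = 3600.0  # s
EVAL_DURATION = 3600.0


@pytest.fixture(scope="session")
def train_bundle():
    """Training network: 100 MAT neurons (80 E / 20 I), 60 min."""
    cfg = netsim.SimConfig.scaled(SCALED_N, duration=TRAIN_DURATION,
                                  seed=TRAIN_SEED)
    rng = np.random.default_rng(TRAIN_SEED)
    net = netsim.build_network(cfg, rng)
    spikes = netsim.simulate(net, cfg, rng)
    return cfg, net, spikes


@pytest.fixture(scope="session")
def eval_bundle():
    """Held-out network with independent wiring and noise, 60 min."""
    cfg = netsim.SimConfig.scaled(SCALED_N, duration=EVAL_DURATION,
                                  seed=EVAL_SEED)
    rng = np.random.default_rng(EVAL_SEED)
    net = netsim.build_network(cfg, rng)
    spikes = netsim.simulate(net, cfg, rng)
    return cfg, net, spikes


@pytest.fixture(scope="session")
def trained_model(train_bundle):
    """CNN trained on the training network's labelled correlograms."""
    _, net, spikes = train_bundle
    data = cnn.make_training_set(spikes, net)
    model = cnn.build_model(cnn.CnnModelSpec(input_length=data.X.shape[1]),
                            np.random.default_rng(MODEL_SEED))
    history = cnn.train(model, data,
                        cnn.TrainConfig(seed=MODEL_SEED, batch_size=64))
    return model, data, history


@pytest.fixture(scope="session")
def eval_estimates(trained_model, eval_bundle):
    """CNN estimate table for every ordered pair of the held-out net."""
    model, _, _ = trained_model
    _, _, spikes = eval_bundle
    return cnn.estimate_matrix(model, spikes)
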