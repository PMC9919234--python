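"""Shared fixtures: the synthetic training corpus and trained fusers.

The expensive session fixtures reproduce the standard study conditions:
four training shapes, forty realisations each, half of the depth tracks
fragmented, both sensors at 10 Hz; evaluation walks follow the occluded
serpentine scenario with 10 Hz radar and 30 Hz depth.
"""

import numpy as np
import pytest

from gaitfuse import (
    DepthModelConfig,
    NetworkSpec,
    RadarNoiseConfig,
    generate_training_set,
    pair_sensor_streams,
    position_errors,
    simulate_walk,
    train_network,
)
from gaitfuse.io import bundled_scenario, training_scenarios

EVAL_SEED = 99


@pytest.fixture(scope="session")
def training_set():
    return generate_training_set(
        training_scenarios(0.7), n_per_traj=40, fragment_fraction=0.5, seed=1
    )


@pytest.fixture(scope="session")
def heldout_walks():
    """Ten occluded serpentine walks never seen in training."""
    scen = bundled_scenario("exp1")
    walks = []
    for r in range(scen.n_realisations):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=EVAL_SEED, spawn_key=(r,)))
        walk = simulate_walk(scen, RadarNoiseConfig(), DepthModelConfig(), True, rng)
        walks.append((walk, pair_sensor_streams(walk.radar, walk.depth)))
    return walks


@pytest.fixture(scope="session")
def mlp_net(training_set):
    return train_network(NetworkSpec("mlp", n_hidden=8), training_set, seed=1)


@pytest.fixture(scope="session")
def narx_net(training_set):
    return train_network(NetworkSpec("narx", n_hidden=6), training_set, seed=1)


def median_meae(tracks_and_refs):
    """Median over walks of the mean absolute position error."""
    return float(
        np.median([position_errors(est, ref).dd.mean() for est, ref in tracks_and_refs])
    )
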