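"""Shared fixtures: one session-scoped end-to-end run and attention sweep.

The heavy simulations (260-trial synthetic study, three-point attention
sweep) run once per session and are shared by every test that inspects
their behaviour.
"""

import logging

import numpy as np
import pytest
from hypothesis import settings

from perceptime import RunConfig, attention_sweep, run_experiment

logging.getLogger("perceptime").setLevel(logging.WARNING)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: Seed for the session-scoped study; every stage derives from it.
STUDY_SEED = 7


@pytest.fixture(scope="session")
def study_config() -> RunConfig:
    return RunConfig(seed=STUDY_SEED, log_level="WARNING")


@pytest.fixture(scope="session")
def stream_bundle(study_config):
    """Full synthetic study: 13 durations x 20 reps, 4 layers, 10-fold CV."""
    return run_experiment(study_config)


@pytest.fixture(scope="session")
def sweep_result(study_config):
    """Attention sweep over C in {0.5, 1, 2} with shared streams and seeds."""
    return attention_sweep(study_config, [0.5, 1.0, 2.0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
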