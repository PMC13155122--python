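"""Shared fixtures: tiny instances, corpora and a pretrained tiny solver.

The expensive fixtures (trained denoiser, uncertainty task) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

from disco.bgnn import DenoiserParams, tiny_config
from disco.oracle import GeneratorConfig, make_corpus, make_instance
from disco.presets import (TINY_MAX_STEPS, tiny_generator, tiny_schedule,
                           tiny_train_config)
from disco.training import LossWeights, train


@pytest.fixture(scope="session")
def tiny_gen_config() -> GeneratorConfig:
    return tiny_generator()


@pytest.fixture(scope="session")
def tiny_instance(tiny_gen_config):
    return make_instance(tiny_gen_config, seed=3)


@pytest.fixture(scope="session")
def small_corpus(tiny_gen_config):
    """A 12-instance corpus for fast unit tests."""
    return make_corpus(12, (8, 1, 1), tiny_gen_config, seed=5)


@pytest.fixture(scope="session")
def tiny_params():
    return DenoiserParams.init(tiny_config(), seed=11)


@pytest.fixture(scope="session")
def recovery_corpus(tiny_gen_config):
    """The desk-scale pretraining corpus: 300 instances split 240/30/30."""
    return make_corpus(300, (8, 1, 1), tiny_gen_config, seed=1)


@pytest.fixture(scope="session")
def trained_params(recovery_corpus):
    """Denoiser pretrained with the desk-scale recipe (2000 updates)."""
    params, _ = train(recovery_corpus, tiny_config(), tiny_train_config(seed=0),
                      LossWeights(), max_steps=TINY_MAX_STEPS)
    return params


@pytest.fixture(scope="session")
def tiny_sched():
    return tiny_schedule()
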