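"""Shared fixtures: simulated trials and corpora, reused across test modules
(session-scoped where generation is expensive)."""

from dataclasses import replace

import numpy as np
import pytest

from gaitid.gaitsim import GaitParams, make_corpus, simulate_trial
from gaitid.identify import train_pipeline
from gaitid.preprocess import preprocess_trial
from gaitid.trial_io import lower_trunk


@pytest.fixture(scope="session")
def nf_params() -> GaitParams:
    """Noise-free study conditions (exact signals, arbitrary mounting)."""
    return GaitParams(noise_sigma_acc=0.0, noise_sigma_gyr=0.0, seed=0)


@pytest.fixture(scope="session")
def nf_sim(nf_params):
    return simulate_trial(nf_params)


@pytest.fixture(scope="session")
def noisy_sim():
    return simulate_trial(GaitParams(seed=3))


@pytest.fixture(scope="session")
def nf_pre(nf_sim):
    return preprocess_trial(nf_sim.trial)


@pytest.fixture(scope="session")
def small_corpus_nf(nf_params):
    return make_corpus(6, seed=42, base_params=nf_params)


@pytest.fixture(scope="session")
def small_model_nf(small_corpus_nf):
    return train_pipeline([s.trial for s in small_corpus_nf])


@pytest.fixture(scope="session")
def lt_corpus_nf(nf_params):
    return make_corpus(6, seed=43, config=lower_trunk(), base_params=nf_params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
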