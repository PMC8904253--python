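"""Shared fixtures: one small synthetic world reused across module tests."""

import numpy as np
import pytest

from neuroprose import synthetic as syn
from neuroprose.types import LagKernel


@pytest.fixture(scope="session")
def vocab():
    return syn.gen_vocabulary(60, 1.05, seed=0)


@pytest.fixture(scope="session")
def events(vocab):
    return syn.gen_word_events(vocab, 400, mean_gap_s=0.3, seed=1)


@pytest.fixture(scope="session")
def static_emb(events):
    return syn.gen_embeddings(events, dim=16, kind="static", seed=2)


@pytest.fixture(scope="session")
def contextual_emb(events):
    return syn.gen_embeddings(
        events, dim=16, kind="contextual", context_strength=0.7, seed=2
    )


@pytest.fixture(scope="session")
def kernel():
    return LagKernel.gaussian(center_ms=150.0, sigma_ms=60.0)


@pytest.fixture(scope="session")
def recording(events, contextual_emb, kernel):
    rec, ledger = syn.gen_neural_recording(
        events, contextual_emb, kernel, n_electrodes=12, fs=128.0, snr=1.0, seed=3
    )
    return rec, ledger
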