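"""Shared fixtures: small, fast synthetic epoch sets.

Tests run at desk scale (12-20 channels, 200-1000 Hz, tens of epochs and
repetitions); package defaults keep the full-size study geometry.
"""

import numpy as np
import pytest
from dataclasses import replace

from assrtag import (
    ATTEND_HIGH,
    ATTEND_LOW,
    DecoderConfig,
    NeuralSimConfig,
    simulate_epochs,
)

SMALL_SIM = NeuralSimConfig(
    n_channels=12,
    fs=200.0,
    epoch_len=1.0,
    n_epochs_per_cond=40,
    assr_amp=0.05,
    attention_gain=2.0,
    noise_white_sd=1.0,
    noise_pink_sd=1.0,
    seed=3,
)

FAST_DECODER = DecoderConfig(n_repeats=20, seed=7)


@pytest.fixture(scope="session")
def effect_epochs():
    """Attention gain 2.0 at both tags: decodable at 39/43 Hz."""
    return simulate_epochs(SMALL_SIM)


@pytest.fixture(scope="session")
def null_epochs():
    """Attention gain 1.0: the two conditions are identically distributed."""
    return simulate_epochs(replace(SMALL_SIM, attention_gain=1.0, seed=11))


@pytest.fixture(scope="session")
def effect_pair(effect_epochs):
    return effect_epochs.select(ATTEND_LOW), effect_epochs.select(ATTEND_HIGH)


@pytest.fixture(scope="session")
def null_pair(null_epochs):
    return null_epochs.select(ATTEND_LOW), null_epochs.select(ATTEND_HIGH)


@pytest.fixture(scope="session")
def effect_spectrum(effect_pair):
    from assrtag import repeated_split_auc

    return repeated_split_auc(*effect_pair, FAST_DECODER)
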