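"""Shared fixtures: a small head model and cohort reused across modules."""

import numpy as np
import pytest

from trusteeg.erp import CognitiveSet
from trusteeg.headmodel import build_head_model, cognitive_channel_indices
from trusteeg.inverse import compute_inverse_operator
from trusteeg.synthdata import (
    ChoiceModel,
    ExperimentSpec,
    NoiseSpec,
    default_effects,
    simulate_decisions,
    simulate_epochs,
)


@pytest.fixture(scope="session")
def lead32():
    """32-channel, 296-dipole spherical lead field (2 dipoles per parcel)."""
    return build_head_model(n_channels=32, n_dipoles=296)


@pytest.fixture(scope="session")
def op32(lead32):
    return compute_inverse_operator(lead32)


@pytest.fixture(scope="session")
def cog32(lead32):
    return CognitiveSet(cognitive_channel_indices(lead32, 26))


@pytest.fixture
def small_spec():
    """Six-participant, 32-channel experiment for fast end-to-end checks."""
    return ExperimentSpec(n_participants=6, n_channels=32, seed=7)


@pytest.fixture(scope="session")
def small_cohort(lead32):
    """Simulated decisions + epochs with the default condition effects."""
    spec = ExperimentSpec(n_participants=6, n_channels=32, seed=7)
    decisions = simulate_decisions(spec, ChoiceModel())
    epochs = simulate_epochs(
        spec, decisions, lead32, default_effects(), NoiseSpec()
    )
    return spec, decisions, epochs


@pytest.fixture(scope="session")
def lead64():
    """64-channel, 592-dipole model: the scale used for effect recovery.

    The 26-electrode cognitive subset is meaningful only against a montage
    substantially denser than itself (with average-referenced data the mean
    over nearly all channels cancels), so effect-sensitive tests run at 64
    channels.
    """
    return build_head_model(n_channels=64, n_dipoles=592)


@pytest.fixture(scope="session")
def cog64(lead64):
    return CognitiveSet(cognitive_channel_indices(lead64, 26))


@pytest.fixture(scope="session")
def effect_cohort(lead64):
    """Eight participants at 64 channels with the default condition effects."""
    spec = ExperimentSpec(n_participants=8, n_channels=64, seed=5)
    decisions = simulate_decisions(spec, ChoiceModel())
    epochs = simulate_epochs(
        spec, decisions, lead64, default_effects(), NoiseSpec()
    )
    return spec, decisions, epochs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
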