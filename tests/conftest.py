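"""Shared fixtures: a simulated 0.1 Hz AC-coupled chain and its characterized UIR.

The heavy fixtures (600 s mixed-sine pipeline) are session-scoped so the
full inverse-filter loop runs once and is examined by several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from isarestore import (
    NoiseSpec,
    RecordingChain,
    add_noise,
    characterize_uir,
    default_chain,
    inverse_filter,
    make_double_step,
    make_mixed_sine,
    make_step,
    simulate_recording,
)

RATE = 1000.0


@pytest.fixture(scope="session")
def chain() -> RecordingChain:
    """First-order 0.1 Hz high-pass chain (the AC amplifier input stage)."""
    return default_chain(0.1)


@pytest.fixture(scope="session")
def step_recorded(chain):
    """Recorded output of a clean unit step (the measured step response)."""
    return simulate_recording(make_step(RATE, 60.0, 10.0), chain)


@pytest.fixture(scope="session")
def uir(step_recorded):
    """UIR characterized from the clean measured step response."""
    return characterize_uir(step_recorded, "measured_step")


@pytest.fixture(scope="session")
def double_step():
    return make_double_step(RATE, 60.0, 10.0, 20.0, 30.0, 40.0)


@pytest.fixture(scope="session")
def double_step_recorded(chain, double_step):
    return simulate_recording(double_step, chain)


@pytest.fixture(scope="session")
def mixed_loop(chain, uir):
    """Full 600 s mixed-sine loop: (input, recorded, reconstruction)."""
    mix = make_mixed_sine(RATE, 600.0)
    rec = simulate_recording(mix, chain)
    recon = inverse_filter(rec, uir)
    return mix, rec, recon
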