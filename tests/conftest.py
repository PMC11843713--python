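"""Shared fixtures: session-scoped simulated streams reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import segtof as st


@pytest.fixture(scope="session")
def default_physics() -> st.PhysicsConfig:
    return st.PhysicsConfig()


@pytest.fixture(scope="session")
def bgo_stream() -> "pandas.DataFrame":
    """Default 15 mm BGO coincidence stream, crosstalk off, 20k events.

    The workhorse stream for timing analyses (CTR vs k, deciles,
    photon-number kernels).
    """
    return st.simulate_and_process(n_events=20_000, seed=2024)


@pytest.fixture(scope="session")
def prompt_stream() -> "pandas.DataFrame":
    """Noise-free prompt-only (Cherenkov) stream with zero transit spread:
    every arrival is coincident with the interaction, so quantized initial
    photon counts must equal true arrival counts exactly."""
    phys = st.PhysicsConfig(
        mean_scint_photons=0.0,
        transit_spread_per_mm=0.0,
        cherenkov_spread=1.0,
    )
    readout = st.ReadoutConfig(noise_sigma=0.0)
    return st.simulate_and_process(
        physics=phys, readout=readout, n_events=400, seed=77
    )
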