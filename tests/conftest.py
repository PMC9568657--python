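"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from hypercoh.io import LeadField, Recording
from hypercoh.synth import CouplingSpec, generate_schedule, simulate_dyad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_schedule():
    """2 blocks x 30 trials, all six fairness x agency cells."""
    return generate_schedule(n_blocks=2, trials_per_block=30, iti_samples=400, seed=7)


@pytest.fixture
def clean_dyad(small_schedule):
    """Noise-free, fully phase-locked dyad on a 3-channel montage."""
    coupling = CouplingSpec(
        kappa=1.0, noise_pink_sigma=0.0, noise_white_sigma=0.0
    )
    return simulate_dyad(
        small_schedule, coupling, channel_names=["Pz", "Cz", "hEOG"], fs=250.0, seed=11
    )


@pytest.fixture
def noisy_dyad(small_schedule):
    """Dyad with the default realistic noise levels."""
    coupling = CouplingSpec(kappa=0.8)
    return simulate_dyad(
        small_schedule, coupling, channel_names=["Pz", "Cz", "hEOG"], fs=250.0, seed=11
    )


@pytest.fixture
def toy_leadfield(rng):
    """Random full-rank 20-channel, 30-dipole lead field."""
    n_ch, n_dip = 20, 30
    return LeadField(
        matrix=rng.standard_normal((n_ch, 3 * n_dip)),
        dipole_positions=rng.uniform(-70, 70, (n_dip, 3)),
        channel_names=[f"ch{i:02d}" for i in range(n_ch)],
    )


def make_recording(
    n_channels=3,
    n_samples=4000,
    fs=250.0,
    markers=(),
    seed=0,
    names=None,
) -> Recording:
    r = np.random.default_rng(seed)
    return Recording(
        data=r.standard_normal((n_channels, n_samples)),
        fs=fs,
        channel_names=names or [f"ch{i}" for i in range(n_channels)],
        markers=list(markers),
        subject_id="test",
    )
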