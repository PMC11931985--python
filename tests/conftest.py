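import numpy as np
import pytest

from statescan.synthetic import (
    double_well_potential,
    generate_two_state_trajectory,
    generate_umbrella_dataset,
    harmonic_potential,
    make_reference_pair,
    make_toy_receptor,
)


@pytest.fixture(scope="session")
def receptor():
    return make_toy_receptor(1)


@pytest.fixture(scope="session")
def reference_pair(receptor):
    """(closed, open) structures differing by an 8 Å TM6 displacement."""
    return make_reference_pair(receptor, tm6_shift=8.0)


@pytest.fixture(scope="session")
def clean_collapse_traj(reference_pair):
    """Noise-free 40-frame open→closed collapse (collapse at frame 10)."""
    closed, open_ = reference_pair
    return generate_two_state_trajectory(
        closed, open_, n_frames=40, collapse_frame=10, noise_sd=0.0, seed=2
    )


@pytest.fixture(scope="session")
def small_harmonic_dataset():
    """Tiny umbrella dataset over a weak harmonic potential (fast WHAM)."""
    pot = harmonic_potential(2.0, 0.0, (-0.6, 0.6))
    return generate_umbrella_dataset(
        pot, n_windows=8, spacing=0.15, force_const=500.0, n_samples=800, seed=5
    ), pot


@pytest.fixture(scope="session")
def small_double_well_dataset():
    pot = double_well_potential(2.0, (0.0, 2.0))
    return generate_umbrella_dataset(
        pot, n_windows=20, spacing=0.1, force_const=1000.0, n_samples=1500, seed=9
    ), pot
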