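import numpy as np
import pytest

from aminogram import SimScenario


@pytest.fixture
def quiet_scenario():
    """Small noise-free cohort with the default kinetics."""
    return SimScenario(seed=7, noise_cv=0.0, n_subjects=2)


@pytest.fixture
def noisy_scenario():
    return SimScenario(seed=7, noise_cv=0.1, n_subjects=4)


@pytest.fixture
def wide_w_scenario():
    """Noise-free scenario whose adjusted hydrolysis ratio sweeps from the
    free-amino-acid regime into near-maximal tripeptide dominance
    (W(t) ~ 1.3 to 2.5, the ceiling at beta_true = 0.15)."""
    return SimScenario(
        seed=13, noise_cv=0.0, n_subjects=2,
        free_amplitude=120.0, free_tau=10.0,
        di_amplitude=25.0, di_tau=30.0,
        tri_amplitude=120.0, tri_tau=90.0,
    )
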