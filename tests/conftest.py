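import numpy as np
import pytest

from slowmodes.generative import HemodynamicParams, integrate_generative
from slowmodes.neural_field import ModeBasis, NeuralFieldParams, default_frequency_grid
from slowmodes.synthetic import CohortSpec, simulate_subject


@pytest.fixture(scope="session")
def params():
    """Default biophysical constants of the neural field."""
    return NeuralFieldParams()


@pytest.fixture(scope="session")
def basis():
    return ModeBasis()


@pytest.fixture(scope="session")
def freqs():
    return default_frequency_grid()


@pytest.fixture(scope="session")
def small_sim():
    """A 3-region, 200-scan simulated dataset with known connectivity and
    block drive, used by the inversion tests."""
    a_true = np.array([[-1.0, 0.4, 0.0], [0.3, -1.0, -0.4], [0.0, 0.5, -1.0]])
    drive = np.zeros((200, 3))
    for start in (20, 60, 100, 150):
        drive[start : start + 8] = np.array([1.0, 0.7, 0.5])
    traj, bold = integrate_generative(
        a_true,
        HemodynamicParams(),
        state_noise_sd=0.05,
        drive=drive,
        n_scans=200,
        TR=3.0,
        dt=0.01,
        seed=11,
    )
    states = traj.x_n[::300][:200]
    rng = np.random.default_rng(12)
    noise_sd = bold.y.std(axis=0).mean()
    y = bold.y + noise_sd * rng.standard_normal(bold.y.shape)
    return {
        "A": a_true,
        "states": states,
        "clean": bold.y,
        "y": y,
        "noise_sd": noise_sd,
        "tr": 3.0,
    }


@pytest.fixture(scope="session")
def subject0():
    """First subject of the default synthetic cohort."""
    spec = CohortSpec()
    seed = int(np.random.SeedSequence(spec.seed).generate_state(1)[0] % (2**31))
    return simulate_subject(spec, seed, subject_id=0)
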