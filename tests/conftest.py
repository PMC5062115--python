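import numpy as np
import pytest

import gelmech as gm


@pytest.fixture(scope="session")
def tip():
    return gm.TipSpec(half_angle_deg=22.0)


@pytest.fixture(scope="session")
def cantilever():
    return gm.Cantilever(spring_constant=0.1, sensitivity=20e-9)


@pytest.fixture(scope="session")
def true_cal(cantilever):
    """Calibration object holding the simulator's exact instrument constants."""
    return gm.Calibration(
        sensitivity=cantilever.sensitivity, spring_constant=cantilever.spring_constant
    )


@pytest.fixture
def noiseless_acq():
    return gm.AcquisitionSpec(deflection_noise_sd=0.0)


@pytest.fixture
def noisy_acq():
    return gm.AcquisitionSpec(deflection_noise_sd=0.5e-9)


@pytest.fixture
def noiseless_curve(tip, cantilever, noiseless_acq):
    gel = gm.GelSpec(young_modulus=200e3, poisson_ratio=0.5)
    return gm.simulate_force_curve(gel, noiseless_acq, tip, cantilever)


def sneddon_prefactor(young_modulus, nu, tip):
    return (2.0 / np.pi) * tip.tan_theta * young_modulus / (1.0 - nu**2)
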