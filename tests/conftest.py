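import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import helixtrack as ht
from helixtrack.imaging import ImagingConfig, generate_calibration_stack
from helixtrack.tracking import fit_z_calibration

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice_13():
    return ht.build_lattice("taxol", 13)


@pytest.fixture(scope="session")
def lattice_14():
    return ht.build_lattice("GMP-CPP", 14)


@pytest.fixture(scope="session")
def lattice_12():
    return ht.build_lattice("taxol", 12)


@pytest.fixture(scope="session")
def imaging_noiseless():
    return ImagingConfig(read_noise_sd=0.0)


@pytest.fixture(scope="session")
def imaging_default():
    return ImagingConfig()


@pytest.fixture(scope="session")
def calibration_noiseless(imaging_noiseless):
    stack = generate_calibration_stack(imaging_noiseless, n_repeats=1)
    return fit_z_calibration(stack)


def clean_helix(pitch_nm=600.0, handedness="right", duration=25.0, seed=0, noise=(0.0, 0.0, 0.0), **kw):
    cfg = ht.CargoSimConfig(
        pitch_program=[(duration, pitch_nm, handedness)], noise_sd_xyz=noise, **kw
    )
    return ht.simulate_cargo(cfg, seed=seed)
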