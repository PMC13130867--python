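import numpy as np
import pytest

from polycalib.fixtures import (
    calibration_relax_settings,
    dipolar_forcefield,
    lj_forcefield,
    make_calibration_triple,
    make_dipolar_crystal,
    make_lj_fcc,
    make_rocksalt,
    rocksalt_forcefield,
)


@pytest.fixture(scope="session")
def rocksalt():
    return make_rocksalt(spacing=2.82, q=1.0), rocksalt_forcefield()


@pytest.fixture(scope="session")
def lj_crystal():
    sigma = 3.4
    return make_lj_fcc(1.55 * sigma, sigma), lj_forcefield(sigma, 1.0)


@pytest.fixture(scope="session")
def dipolar():
    return make_dipolar_crystal(4.8, 0.3), dipolar_forcefield()


@pytest.fixture(scope="session")
def calibration():
    structures, targets, pvec = make_calibration_triple()
    return structures, targets, pvec, calibration_relax_settings()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
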