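import numpy as np
import pytest

from ecapmap import (
    FittingMap,
    PatientProfile,
    clin_map_of,
    make_virtual_patient,
    set_thr_from_mcl,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def patient():
    """Default adult virtual patient."""
    return make_virtual_patient(42)


@pytest.fixture
def quiet_patient():
    """Noise-free patient: exact artifact cancellation and exact thresholds."""
    return make_virtual_patient(42, PatientProfile(noise_rms=0.0))


@pytest.fixture
def clin(patient):
    return clin_map_of(patient)


def make_map(label="ClinMAP", mcl=None, active=None, volume=90.0):
    """Small helper building a valid 12-channel map with the 10% THR rule."""
    mcl = np.full(12, 20.0) if mcl is None else np.asarray(mcl, dtype=float)
    active = np.ones(12, dtype=bool) if active is None else np.asarray(active, bool)
    return set_thr_from_mcl(
        FittingMap(label=label, mcl=mcl, thr=np.zeros(12), active=active, volume=volume)
    )
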