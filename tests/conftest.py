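import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svdose import KidneyRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_record(
    sv_doses,
    wkp=1.0,
    patient="P01",
    side="left",
    filt=0.0,
    vol=2.0,
    true=None,
):
    return KidneyRecord(
        patient_id=patient,
        kidney_side=side,
        filter_sigma_mm=filt,
        sv_volume_ml=vol,
        wkp_dose_gy=wkp,
        sv_doses_gy=tuple(sv_doses),
        true_dose_gy=true,
    )


@pytest.fixture
def hand_records():
    """Two kidneys with hand-picked doses for exact-arithmetic checks."""
    return [
        make_record([1.0, 1.2], wkp=1.0, patient="P01", side="left"),
        make_record([0.9, 1.1], wkp=1.0, patient="P01", side="right"),
    ]
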