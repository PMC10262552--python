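import pytest

from polytdm.pk_model import PKParameters, Regimen
from polytdm.synthetic_cohort import VirtualPatient


@pytest.fixture
def two_cpt_params() -> PKParameters:
    return PKParameters(
        clearance=2.0,
        central_volume=12.0,
        intercompartmental_clearance=6.0,
        peripheral_volume=20.0,
    )


@pytest.fixture
def hd_regimen() -> Regimen:
    return Regimen(loading_dose=150.0, maintenance_dose=75.0)


def make_patient(clearance: float = 2.0, **overrides) -> VirtualPatient:
    fields = dict(
        id="T0001",
        sex="male",
        age=60.0,
        weight=70.0,
        bmi=24.0,
        baseline_scr=80.0,
        septic_shock=False,
        on_crrt=False,
        infection_sites=("pulmonary",),
        pathogen="CRAB",
        pathogen_mic=1.0,
        baseline_sofa=7,
        pk=PKParameters(clearance, 12.0, 6.0, 20.0),
    )
    fields.update(overrides)
    return VirtualPatient(**fields)


@pytest.fixture
def patient_factory():
    return make_patient
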