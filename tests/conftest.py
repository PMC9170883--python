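import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alpharecist.cohort import (
    AFPPair,
    Cohort,
    LesionMeasurement,
    NontargetStatus,
    PatientRecord,
    SurvivalOutcome,
    Timepoint,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_patient(
    pid: str,
    sld_bl: float,
    sld_fu: float,
    afp_bl: float | None = None,
    afp_fu: float | None = None,
    viable_frac: float = 0.8,
    viable_fu: float | None = None,
    new_lesions: bool = False,
    nontarget: NontargetStatus = NontargetStatus.ABSENT,
    rfs: tuple[float, bool] = (24.0, False),
    os_: tuple[float, bool] | None = None,
) -> PatientRecord:
    """Single-lesion patient with the given sums of diameters."""
    os_ = os_ or (rfs[0], rfs[1])
    v_bl = sld_bl * viable_frac
    v_fu = min(sld_fu * viable_frac, sld_fu) if viable_fu is None else viable_fu
    lesions = (
        LesionMeasurement("L1", "liver", Timepoint.BASELINE, sld_bl, v_bl, True),
        LesionMeasurement("L1", "liver", Timepoint.FOLLOWUP, sld_fu, v_fu, True),
    )
    afp = AFPPair(afp_bl, afp_fu) if afp_bl is not None else None
    return PatientRecord(
        patient_id=pid,
        lesions=lesions,
        new_lesions=new_lesions,
        nontarget_status=nontarget,
        survival=SurvivalOutcome(rfs[0], rfs[1], os_[0], os_[1]),
        afp=afp,
    )


@pytest.fixture
def example_cases_cohort() -> Cohort:
    """Three worked-example patients: size/AFP changes
    (-42%, -95.8%), (-34%, -15%), (-17%, -97.4%)."""
    return Cohort(records=[
        make_patient("case1", 100.0, 58.0, afp_bl=1000.0, afp_fu=42.0),
        make_patient("case2", 100.0, 66.0, afp_bl=100.0, afp_fu=85.0),
        make_patient("case3", 100.0, 83.0, afp_bl=1000.0, afp_fu=26.0),
    ])


@pytest.fixture
def textbook_survival():
    """Six subjects, times {6, 6, 6, 7+, 10, 10+} (+ = censored)."""
    times = np.array([6.0, 6.0, 6.0, 7.0, 10.0, 10.0])
    events = np.array([True, True, True, False, True, False])
    return times, events
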