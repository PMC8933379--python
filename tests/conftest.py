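import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abspk.datamodel import (
    Analyte,
    AnalyteSpec,
    ConcentrationPoint,
    DoseEvent,
    PKProfile,
    Route,
    Treatment,
    TreatmentSequence,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_profile(times, concs, *, treatment=Treatment.IV, dose_mg=50.0,
                 infusion_duration=1.25, subject_id="S01", period=1,
                 sequence=TreatmentSequence.IV_THEN_ORAL,
                 analyte=Analyte.PARENT, blq=None):
    """Build a PKProfile from parallel time/concentration lists."""
    if treatment is Treatment.IV:
        dose = DoseEvent(Route.IV_INFUSION, dose_mg, infusion_duration)
    else:
        dose = DoseEvent(Route.ORAL, dose_mg)
    blq = blq or [False] * len(times)
    pts = tuple(
        ConcentrationPoint(t, t, c, b) for t, c, b in zip(times, concs, blq)
    )
    return PKProfile(subject_id=subject_id, sequence=sequence, period=period,
                     treatment=treatment, analyte=analyte, dose=dose,
                     points=pts)


@pytest.fixture
def parent_spec():
    return AnalyteSpec(name="parent", molecular_weight=406.4, lloq=2.50)


@pytest.fixture
def metabolite_spec():
    return AnalyteSpec(name="metabolite", molecular_weight=203.2, lloq=2.50)
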