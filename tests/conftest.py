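from datetime import datetime

import pytest

from bilinorm.decision_engine import PatientRecord, RiskFactor, TSBUnit
from bilinorm.guideline_tables import load_default_guideline


@pytest.fixture(scope="session")
def guideline():
    return load_default_guideline()


@pytest.fixture
def worked_example_patient():
    """Preterm infant, 33 weeks, 2100 g, day 2, ABO incompatibility, TSB 17.2."""
    birth = datetime(2019, 3, 1, 8, 0)
    return PatientRecord(
        ga_weeks=33,
        birth_datetime=birth,
        record_datetime=datetime(2019, 3, 3, 8, 0),
        bw_g=2100,
        tsb_value=17.2,
        tsb_unit=TSBUnit.MG_DL,
        risk_factors=frozenset({RiskFactor.ABO_RH_INCOMPATIBILITY}),
    )
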