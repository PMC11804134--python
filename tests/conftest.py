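import numpy as np
import pytest

from metsrisk.cohort import MetabolicPanel, ParticipantRecord
from metsrisk.risk_model import PredictorSpec, RiskModel
from metsrisk.simulate import default_true_model


@pytest.fixture(scope="session")
def full_model() -> RiskModel:
    """Packaged synthetic reference model, full variant."""
    return default_true_model("full")


@pytest.fixture(scope="session")
def partial_model() -> RiskModel:
    return default_true_model("partial")


@pytest.fixture
def toy_model() -> RiskModel:
    """Small hand-built model for arithmetic checks."""
    return RiskModel(
        name="toy",
        variant="partial",
        site="UK",
        intercept=-2.0,
        predictors=(
            PredictorSpec(name="exposed", kind="binary", coefficient=2.0),
        ),
    )


def make_record(
    id="P1",
    age=22.0,
    sex="male",
    waist=85.0,
    bmi=24.0,
    hdl=1.4,
    triglycerides=1.1,
    sbp=118.0,
    dbp=74.0,
    glucose=4.9,
    followup=None,
    followup_years=2.5,
    **kwargs,
):
    baseline = MetabolicPanel(
        bmi=bmi,
        waist=waist,
        sbp=sbp,
        dbp=dbp,
        triglycerides=triglycerides,
        hdl=hdl,
        fasting_glucose=glucose,
    )
    return ParticipantRecord(
        id=id,
        age=age,
        sex=sex,
        born_in_australia=kwargs.pop("born_in_australia", True),
        smoker=kwargs.pop("smoker", False),
        antipsychotic_class=kwargs.pop("antipsychotic_class", "higher_metabolic"),
        ethnicity=kwargs.pop("ethnicity", "white"),
        baseline=baseline,
        baseline_offset_days=kwargs.pop("baseline_offset_days", 0),
        followup=followup if followup is not None else baseline,
        followup_years=followup_years,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record
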