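import pytest

from phclinic import default_rule_table
from phclinic.synthetic_cohort import calibrate_config, default_config

#: published fractions of subjects graded yellow-or-worse per item
PREVALENCE_TARGETS = {
    "waist_hip_ratio": 0.6498,
    "blood_pressure": 0.3306,
    "blood_sugar": 0.0837,
}


@pytest.fixture(scope="session")
def rules():
    return default_rule_table()


@pytest.fixture(scope="session")
def calibrated_config(rules):
    """Default cohort config calibrated to the published item prevalences."""
    cfg = default_config(seed=1)
    return calibrate_config(cfg, PREVALENCE_TARGETS, rules, n_calib=50_000)


def make_record_kwargs(**overrides):
    """A minimal valid subject record, overridable per test."""
    base = {"subject_id": "S1", "age": 40, "sex": "male", "area": "rural"}
    base.update(overrides)
    return base
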