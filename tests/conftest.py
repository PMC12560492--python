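import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import seqmediate as sm

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("deterministic")


def _record(**kw):
    """One participant row with benign defaults; overrides via kwargs."""
    base = {
        "participant_id": 0,
        "baseline_age": 50.0, "sex": "M", "center": "C01",
        "education_years": 15.0, "birth_year": 1964.0,
        "cts_1": 1.0, "cts_2": 1.0, "cts_3": 1.0, "cts_4": 5.0, "cts_5": 5.0,
        "ever_smoked": 0.0, "smoking_init_age": np.nan, "smoking_quit_age": np.nan,
        "weight_at_10": "regular", "weight_kg_18": 56.32,  # BMI 22 at height 1.6
        "weight_kg_30": np.nan, "weight_kg_50": np.nan,
        "baseline_weight_kg": 60.0, "baseline_height_m": 1.6,
        "cancer_site": None,
        **{f"diagnosed_{d}": 0.0 for d in sm.cohort_derivation.DISEASES},
        **{f"age_at_dx_{d}": np.nan for d in sm.cohort_derivation.DISEASES},
        "_gen_ever_smoking": 0.0, "_gen_early_overweight": 0.0,
    }
    base.update(kw)
    return base


@pytest.fixture
def hand_cohort() -> pd.DataFrame:
    """Ten hand-built participants exercising every derivation rule.

    With disease = MI and the ever-smoking mediator the exclusion ledger is
    exactly {missing_cts: 2, missing_diagnosis_age: 1, diagnosed_before_18: 1}
    (6 retained rows); under current smoking, one additional row is excluded
    for quitting before the diagnosis.
    """
    rows = [
        # 1: abused, never smoker, no diagnosis
        _record(participant_id=1, cts_1=3.0),
        # 2-3: missing / out-of-range CTS
        _record(participant_id=2, cts_1=np.nan),
        _record(participant_id=3, cts_3=7.0),
        # 4: diagnosed before 18
        _record(participant_id=4, diagnosed_mi=1.0, age_at_dx_mi=15.0),
        # 5: case without an age at diagnosis
        _record(participant_id=5, diagnosed_mi=1.0),
        # 6: smoked 16-30, diagnosed at 40: ever -> 1, current -> excluded
        _record(participant_id=6, ever_smoked=1.0, smoking_init_age=16.0,
                smoking_quit_age=30.0, diagnosed_mi=1.0, age_at_dx_mi=40.0),
        # 7: initiation after the diagnosis: coded 0
        _record(participant_id=7, ever_smoked=1.0, smoking_init_age=45.0,
                diagnosed_mi=1.0, age_at_dx_mi=40.0),
        # 8: never smoker, case at 40
        _record(participant_id=8, diagnosed_mi=1.0, age_at_dx_mi=40.0),
        # 9: overweight via age-10 report only (early 1, 18+ 0), baseline 35
        _record(participant_id=9, weight_at_10="higher", baseline_age=35.0,
                birth_year=1979.0),
        # 10: BMI exactly 25.0 at 18 (25 * 1.6^2 kg at 1.6 m), case at 35
        _record(participant_id=10, weight_kg_18=25.0 * 1.6**2, diagnosed_mi=1.0,
                age_at_dx_mi=35.0),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """A calibrated 120k-participant cohort shared across tests."""
    config = sm.calibrated_config(120_000, seed=11)
    return config, sm.generate_cohort(config, seed=11)
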