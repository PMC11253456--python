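import numpy as np
import pandas as pd
import pytest

from chegap.che import che_flag
from chegap.survey import ExpenditureProfile, HouseholdRecord, records_to_frame
from chegap.synthetic import OUTCOME_COVARIATES, SyntheticConfig, generate_outcome_level


def make_record(**overrides) -> HouseholdRecord:
    defaults = dict(
        household_id="hh0001",
        kebele="01",
        head_sex="male",
        head_age=40,
        marital_status="married",
        occupation="self_employed",
        family_size=4,
        u5_present="no",
        ownership="private",
        insurance="insured",
        chronic_condition="no",
        traditional_medicine="no",
        referral_history="no",
        expenditure=ExpenditureProfile(
            food=40000.0, nonfood_nonhealth=20000.0,
            direct_medical=3000.0, direct_nonmedical=500.0,
            lost_days=4.0, daily_valuation=100.0,
        ),
    )
    defaults.update(overrides)
    return HouseholdRecord(**defaults)


def outcome_frame(records) -> pd.DataFrame:
    """Analysis frame with the CHE flag decoded from expenditure profiles."""
    frame = records_to_frame(records)
    frame["che"] = [
        "yes" if che_flag(r.expenditure).catastrophic else "no" for r in records
    ]
    return frame


@pytest.fixture(scope="session")
def outcome_sample():
    """Default-condition outcome-level sample (n = 194 / 631) with truth."""
    records, truth = generate_outcome_level(SyntheticConfig(seed=20220524))
    return records, truth


@pytest.fixture(scope="session")
def large_outcome_sample():
    """A larger sample for estimator checks (n = 2000 per group)."""
    cfg = SyntheticConfig(seed=7, n_insured=2000, n_non_insured=2000)
    records, truth = generate_outcome_level(cfg)
    return records, truth, cfg


@pytest.fixture(scope="session")
def covariates():
    return list(OUTCOME_COVARIATES)
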