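import numpy as np
import pytest

from dietval import BmrCoefficientTable, SimulationConfig, Subject, WeightStatusCutoffs
from dietval.energy import BmrRow


@pytest.fixture
def girl() -> Subject:
    """A child with the sample's mean anthropometrics."""
    return Subject("G01", "F", 10.3, 35.5, 144.0, 2)


@pytest.fixture
def boy() -> Subject:
    return Subject("B01", "M", 10.3, 35.5, 144.0, 2)


@pytest.fixture
def flat_bmr_table() -> BmrCoefficientTable:
    """Synthetic coefficient table with easy arithmetic (both sexes, 5-18 y)."""
    return BmrCoefficientTable(
        rows=[
            BmrRow(sex, 5.0, 18.0, 0.1, 1.0, 2.0) for sex in ("M", "F")
        ],
        source="synthetic",
    )


@pytest.fixture
def simple_cutoffs() -> WeightStatusCutoffs:
    """Synthetic BMI cut-off table with round numbers."""
    import pandas as pd

    tab = pd.DataFrame(
        {"age": [8.0, 10.0, 12.0], "overweight": [18.0, 20.0, 22.0],
         "obese": [22.0, 24.0, 26.0]}
    )
    return WeightStatusCutoffs(male=tab.copy(), female=tab.copy(), source="synthetic")


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Small noiseless study configuration for exact-value checks."""
    return SimulationConfig(
        n_subjects=4,
        cpm_within_sd=0.0,
        zero_minute_prob=0.0,
        nonwear_gaps_per_day=0.0,
        day_cv=0.0,
        incomplete_day_prob=0.0,
        ratio_subject_sd_pct=0.0,
        ratio_resid_sd_pct=0.0,
        beta_illness_pct=0.0,
        beta_boy_pct=0.0,
        beta_bmi_pct=0.0,
        illness_prob_baseline=0.0,
        illness_prob_intervention=0.0,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
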