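import numpy as np
import pandas as pd
import pytest

from propmort import cohort_model
from propmort.synthetic_cohort import CohortParams, HazardSpec, simulate_cohort

SITES = ["Breast, All", "Lung, All", "Colon/Rectum"]
STAGES4 = ["I", "II", "III", "IV"]
_INDEX_PROB = {"I": 0.03, "II": 0.05, "III": 0.12, "IV": 0.35}


def simple_params(n_cases: int, seed: int, loss_prob: float = 0.0,
                  max_followup_months: int = 179,
                  plateau: bool = False) -> CohortParams:
    """Compact study conditions: 3 sites x 4 stages, time-constant hazards.

    With constant hazards (no plateau, no age slope) the yearly cause
    mixture equals the eventual cause mixture, so loss-year imputation and
    tail extrapolation are exactly unbiased and any systematic recovery
    failure indicates an engine defect.
    """
    mixture = {(s, st): 1.0 / (len(SITES) * len(STAGES4))
               for s in SITES for st in STAGES4}
    hazards = {}
    for (site, stage) in mixture:
        p = _INDEX_PROB[stage]
        specs = [
            HazardSpec("index", p, plateau_year=10 if plateau else None,
                       plateau_prob=0.1 * p if plateau else None),
            HazardSpec("Leukemia", 0.004),
            HazardSpec("Diseases of Heart", 0.010),
            HazardSpec("Chronic Obstructive Pulmonary Disease and Allied Conditions",
                       0.004),
        ]
        hazards[(site, stage)] = specs
    return CohortParams(
        n_cases=n_cases, mixture=mixture, hazards=hazards,
        age_dist={"60-64": 0.5, "70-74": 0.5},
        sex_dist={"Female": 1.0},
        race_dist={"White, Non-Hispanic": 0.6, "Hispanic": 0.4},
        max_followup_months=max_followup_months,
        loss_prob=loss_prob, seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=20,000 cohort with cause-independent censoring plus its latent truth."""
    params = simple_params(20_000, seed=1234, loss_prob=0.04)
    cases, truth = simulate_cohort(params)
    return params, cases, truth


@pytest.fixture(scope="session")
def small_classified():
    """A small fully classified cohort for table and allocation tests."""
    params = simple_params(4_000, seed=7, loss_prob=0.03)
    cases, truth = simulate_cohort(params)
    classified = cohort_model.classify_cohort(cases)
    return classified, truth


def hand_cohort() -> pd.DataFrame:
    """A 12-case hand-built cohort covering all vital statuses."""
    rows = [
        # case_id, site, stage, followup, status, cod
        ("a01", "Breast, All", "I", 6, "dead", "Breast"),
        ("a02", "Breast, All", "I", 30, "dead", "Diseases of Heart"),
        ("a03", "Breast, All", "I", 30, "dead", "Lung"),
        ("a04", "Breast, All", "I", 28, "dead", "Breast"),
        ("a05", "Breast, All", "I", 30, "lost", None),
        ("a06", "Breast, All", "I", 100, "alive", None),
        ("a07", "Breast, All", "I", 95, "dead", "Diseases of Heart"),
        ("a08", "Breast, All", "I", 90, "dead", "Breast"),
        ("b01", "Lung, All", "IV", 3, "dead", "Lung"),
        ("b02", "Lung, All", "IV", 10, "dead", "Lung"),
        ("b03", "Lung, All", "IV", 20, "dead", "Diseases of Heart"),
        ("b04", "Lung, All", "IV", 40, "alive", None),
    ]
    return pd.DataFrame({
        "case_id": [r[0] for r in rows],
        "site_group": [r[1] for r in rows],
        "stage": [r[2] for r in rows],
        "age_group": "60-64",
        "sex": "Female",
        "race_ethnicity": "Hispanic",
        "dx_year": 2006,
        "followup_months": [r[3] for r in rows],
        "vital_status": [r[4] for r in rows],
        "cod_code": [r[5] for r in rows],
    })


@pytest.fixture
def tiny_classified():
    return cohort_model.classify_cohort(hand_cohort())
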