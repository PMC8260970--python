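"""Shared fixtures: one simulated cohort per group with fitted curves.

Session-scoped so the moderately expensive GAM fits run once.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

import threshcurve as tc

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def cirrhosis_config():
    return tc.SimulationConfig.cirrhosis_like(seed=1)


@pytest.fixture(scope="session")
def cirrhosis_cohort(cirrhosis_config):
    return tc.generate_cohort(cirrhosis_config)


@pytest.fixture(scope="session")
def cirrhosis_analysis(cirrhosis_cohort):
    analysis, _ = tc.apply_exclusions(cirrhosis_cohort)
    return analysis


@pytest.fixture(scope="session")
def fibrosis_config():
    return tc.SimulationConfig.fibrosis_like(seed=1)


@pytest.fixture(scope="session")
def fibrosis_analysis(fibrosis_config):
    analysis, _ = tc.apply_exclusions(tc.generate_cohort(fibrosis_config))
    return analysis


@pytest.fixture(scope="session")
def gam90(cirrhosis_analysis):
    return tc.AdjustedMortalityGAM(cirrhosis_analysis, horizon=90).fit()


@pytest.fixture(scope="session")
def gam28(cirrhosis_analysis):
    return tc.AdjustedMortalityGAM(cirrhosis_analysis, horizon=28).fit()


@pytest.fixture(scope="session")
def curve90(gam90):
    return gam90.predict_curve()


@pytest.fixture(scope="session")
def curve28(gam28):
    return gam28.predict_curve()


def make_toy_cohort(tb, death_90, death_28=None, time_to_death=None, **overrides):
    """Minimal schema-complete cohort table for unit tests."""
    n = len(tb)
    death_90 = np.asarray(death_90, dtype=int)
    if death_28 is None:
        death_28 = np.zeros(n, dtype=int)
    if time_to_death is None:
        time_to_death = np.where(death_90 == 1, 30.0, 200.0)
    base = {
        "id": np.arange(1, n + 1),
        "age": np.full(n, 50.0),
        "sex": np.ones(n, dtype=int),
        "etiology": np.array(["HBV"] * n, dtype=object),
        "cirrhosis_status": np.array(["compensated"] * n, dtype=object),
        "prior_decompensation_flag": np.zeros(n, dtype=int),
        "ascites": np.zeros(n, dtype=int),
        "gi_bleeding": np.zeros(n, dtype=int),
        "infection": np.zeros(n, dtype=int),
        "he_grade": np.zeros(n, dtype=int),
        "tb": np.asarray(tb, dtype=float),
        "inr": np.full(n, 1.5),
        "creatinine": np.full(n, 0.8),
        "alt": np.full(n, 60.0),
        "ast": np.full(n, 80.0),
        "sodium": np.full(n, 138.0),
        "albumin": np.full(n, 30.0),
        "platelets": np.full(n, 80.0),
        "hemoglobin": np.full(n, 110.0),
        "time_to_death": np.asarray(time_to_death, dtype=float),
        "death_90": death_90,
        "death_28": np.asarray(death_28, dtype=int),
        "lt_within_90": np.zeros(n, dtype=int),
        "lt_day": np.full(n, np.nan),
    }
    base.update(overrides)
    return pd.DataFrame(base)
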