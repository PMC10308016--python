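import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from weightmix import (CheckupRecord, GeneratorConfig, LifestyleProfile,
                       generate_cohort, load_published_model)
from weightmix.model import LeafFormula, PiecewiseLinearModel


@pytest.fixture(scope="session")
def published():
    return load_published_model()


@pytest.fixture(scope="session")
def small_cohort():
    """300 persons under study-like conditions (noise, missingness)."""
    return generate_cohort(GeneratorConfig(n_persons=300, seed=5))


@pytest.fixture(scope="session")
def clean_cohort():
    """600 persons, noisy but fully observed (no missingness)."""
    return generate_cohort(GeneratorConfig(n_persons=600, seed=7,
                                           noise_sd_kg=1.0,
                                           missingness_prob=0.0))


def make_history(weight_m1=90.0, weight_0=90.0, height=170.0, age=40,
                 sex="male", profile=None, person_id="p0"):
    """(year −1, year 0) record pair for trajectory tests."""
    profile = profile or LifestyleProfile()
    rec = lambda y, w: CheckupRecord(
        person_id=person_id, year_index=y, sex=sex, age_years=age,
        height_cm=height, weight_kg=w, lifestyle=profile)
    return rec(-1, weight_m1), rec(0, weight_0)


def single_leaf_model(bias=0.0, terms=None):
    leaf = LeafFormula(formula_id=1, bias=bias,
                       terms=dict(terms or {"weight_baseline": 1.0}))
    return PiecewiseLinearModel(tree=1, leaves={1: leaf},
                                meta={"version": "test"})


# profiles that zero out every indicator of formula 1 (baseline interview at
# year 0, predictive-year answers with intention level 2)
FORMULA1_SILENT_BASE = LifestyleProfile(
    wants_instruction=1, heavy_smoker=1, fast_walker=1, daily_activity=1,
    exercise_habit=1, skips_breakfast=0, late_supper=0, snacks=0,
    sleeps_well=1, drinking_score=0.0, eating_speed=2, intention_level=2)
FORMULA1_SILENT_PRED = LifestyleProfile(
    wants_instruction=0, heavy_smoker=1, fast_walker=0, daily_activity=0,
    exercise_habit=0, skips_breakfast=1, late_supper=1, snacks=1,
    sleeps_well=0, drinking_score=0.0, eating_speed=0, intention_level=2)


def rng(seed=0):
    return np.random.default_rng(seed)
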