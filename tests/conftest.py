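import datetime as dt

import numpy as np
import pytest

from itscount.io import EpisodeRecord
from itscount.simulate import ScenarioConfig, TrueModelParams, simulate_monthly_counts

# canonical study conditions: a large urban subgroup, ~110 visits/month from
# a population of 2.4 million, mild annual seasonality and overdispersion
POPULATION = 2_400_000.0
STUDY_YEARS = range(2016, 2023)


def default_params(effect_by_year=None, **overrides) -> TrueModelParams:
    kw = dict(beta0=-10.0, beta_trend=0.002, harmonics=((0.1, 0.05),),
              dispersion=50.0, effect_by_year=effect_by_year or {})
    kw.update(overrides)
    return TrueModelParams(**kw)


def default_scenario(seed=0, subgroup="adult_male") -> ScenarioConfig:
    return ScenarioConfig(start=(2016, 1), end=(2022, 12), intervention=(2020, 1),
                          population_by_year={y: POPULATION for y in STUDY_YEARS},
                          subgroup=subgroup, seed=seed)


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def scenario():
    return default_scenario()


@pytest.fixture
def series(params, scenario):
    return simulate_monthly_counts(params, scenario)


@pytest.fixture
def offset84():
    return np.full(84, POPULATION)


def make_episode(date=dt.date(2016, 1, 15), sex="female", age=30,
                 mental_health=frozenset(), death28=False, pay_assist=False,
                 triage=3) -> EpisodeRecord:
    return EpisodeRecord(attendance_date=date, sex=sex, age=age,
                         mental_health=frozenset(mental_health), death28=death28,
                         pay_assist=pay_assist, triage=triage)
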