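import datetime as dt

import pandas as pd
import pytest

import hipfrax as hf
import hipfrax.io as hio


@pytest.fixture(scope="session")
def default_rules() -> hf.FilterRules:
    return hf.FilterRules(window_start=dt.date(2011, 1, 1),
                          window_end=dt.date(2012, 12, 31))


@pytest.fixture(scope="session")
def sim_default():
    """One default-preset synthetic registry at a fixed seed."""
    params = hf.SimulationParams(seed=20110101)
    cases, truth = hf.simulate_registry(params)
    return params, cases, truth


@pytest.fixture(scope="session")
def mortality_table() -> pd.DataFrame:
    return hio.read_table(hio.bundled_data_path("mortality_belarus_like_synthetic.csv"),
                          "mortality")


@pytest.fixture(scope="session")
def ratio_table() -> pd.DataFrame:
    return hio.read_table(hio.bundled_data_path("mof_hip_ratios_synthetic.csv"),
                          "ratios")


@pytest.fixture(scope="session")
def standard_table() -> pd.DataFrame:
    return hio.read_table(hio.bundled_data_path("world_standard_2010_synthetic.csv"),
                          "standard")


@pytest.fixture(scope="session")
def target_population() -> pd.DataFrame:
    return hio.read_table(hio.bundled_data_path("target_population_2015_synthetic.csv"),
                          "population")


def make_case(case_id="C1", person_id="P1", sex="female", age=70,
              date=dt.date(2011, 6, 1), resident=True, mechanism="low_energy",
              pathological=False, site="hip_left", hospitalized=True,
              source="hospital") -> hf.FractureCase:
    return hf.FractureCase(case_id=case_id, person_id=person_id, sex=sex,
                           age_years=age, event_date=date, resident=resident,
                           mechanism=mechanism, pathological=pathological,
                           site=site, hospitalized=hospitalized, source=source)


@pytest.fixture
def case_factory():
    return make_case
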