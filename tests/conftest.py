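import numpy as np
import pandas as pd
import pytest

from zoipanc.data_model import build_design_matrix
from zoipanc.fit import fit_zoip
from zoipanc.simulate import SyntheticConfig, generate_pooled_dataset

# a pooled synthetic dataset scaled to ~2500 records for fast fixture fits
SMALL_N = {"2011": 700, "2014": 600, "2017-18": 600, "2022": 600}

REFERENCE_RECORD = dict(
    sanc_visits=0, survey_year="2011", residence="urban", maternal_age="<20",
    maternal_edu="none", paternal_edu="none", wealth="poor", birth_order="first",
    working="non_working", media="non_exposed", decision="no",
    violence_opinion="non_justified", wanted_pregnancy="no",
    terminated_pregnancy="no")


def make_records(*overrides: dict) -> pd.DataFrame:
    """Analysis-mode records: the all-reference profile with row overrides."""
    rows = [{**REFERENCE_RECORD, **ov} for ov in (overrides or ({},))]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, n_per_year=dict(SMALL_N))


@pytest.fixture(scope="session")
def small_df(small_config):
    return generate_pooled_dataset(small_config)[0]


@pytest.fixture(scope="session")
def standard_design(small_df):
    return build_design_matrix(small_df)


@pytest.fixture(scope="session")
def standard_fit(standard_design):
    fit = fit_zoip(standard_design)
    assert fit.converged
    return fit
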