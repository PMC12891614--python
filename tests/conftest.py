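"""Shared fixtures: one small synthetic world and survey campaign, built once."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from reefstress.matching import match_surveys
from reefstress.response_models import ModelSpec, analysis_table
from reefstress.synthetic_data import (
    SurveyDesign,
    build_world,
    default_truth,
    default_world_config,
    generate_surveys,
    harmonize_raw,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def world_cfg():
    return default_world_config(seed=0)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def world(world_cfg, truth):
    return build_world(world_cfg, truth)


@pytest.fixture(scope="session")
def survey_bundle(world, truth):
    """(raw records, truth table) for the default unbiased campaign."""
    return generate_surveys(world, truth, SurveyDesign(n_surveys=600), seed=11)


@pytest.fixture(scope="session")
def harmonized(survey_bundle):
    raw, _ = survey_bundle
    return harmonize_raw(raw)


@pytest.fixture(scope="session")
def matched(world, harmonized):
    return match_surveys(
        harmonized, world.heat, world.ymax_lookup, world.grid, world.stations
    )


@pytest.fixture(scope="session")
def obs_bleach(matched):
    return analysis_table(matched, "moderate_bleach")


@pytest.fixture(scope="session")
def glmm_fixture():
    """750-row synthetic grouped binary fixture with stored R oracle fits."""
    return pd.read_csv(DATA_DIR / "synthetic_glmm_fixture.csv")


@pytest.fixture(scope="session")
def glmm_obs(glmm_fixture):
    d = glmm_fixture
    return pd.DataFrame(
        {
            "dhw": d["dhw"],
            "basin": "AP",
            "bleaching_year": "2014-15",
            "y": d["y"],
            "station_id": d["group"],
            "depth_m": np.nan,
        }
    )


@pytest.fixture(scope="session")
def truth_spec():
    """The spec matching the default truth's coefficient structure."""
    return ModelSpec(
        outcome="moderate_bleach",
        terms=frozenset({"dhw", "basin", "year", "dhw:basin", "dhw:year"}),
    )


@pytest.fixture(scope="session")
def bleach_model(obs_bleach, truth_spec):
    """The truth-structured mixed model fitted once on the default campaign."""
    from reefstress.response_models import fit_model

    return fit_model(obs_bleach, truth_spec)
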