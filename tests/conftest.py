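import numpy as np
import pandas as pd
import pytest

from ruralgap.dataset import SurveyDataset
from ruralgap.synthetic import CountryConfig, SimulationConfig, generate_survey


def make_country(
    name="A",
    n_clusters=60,
    children_per_cluster=50,
    rural_cluster_fraction=0.65,
    intercept=-2.0,
    rural_effect=0.0,
    edu_shift=0.25,
    wealth_shift=-1.0,
    cluster_sd=0.25,
    weight_cv=0.25,
    **overrides,
):
    kwargs = dict(
        name=name,
        n_clusters=n_clusters,
        children_per_cluster=children_per_cluster,
        rural_cluster_fraction=rural_cluster_fraction,
        intercept=intercept,
        rural_effect=rural_effect,
        covariate_effects={"no_education": 0.8, "unemployed": 0.3, "wealth": -0.15},
        covariate_rural_shift={"no_education": edu_shift, "wealth": wealth_shift},
        covariate_base={"no_education": 0.3, "unemployed": 0.4},
        covariate_kind={"wealth": "ordinal5"},
        cluster_sd=cluster_sd,
        weight_cv=weight_cv,
    )
    kwargs.update(overrides)
    return CountryConfig(**kwargs)


@pytest.fixture(scope="session")
def three_country_config():
    return SimulationConfig(
        countries=[
            make_country("Alpha", rural_effect=0.4),
            make_country("Beta", rural_effect=0.0),
            make_country("Gamma", rural_effect=-0.3),
        ],
        seed=42,
    )


@pytest.fixture(scope="session")
def three_country_data(three_country_config):
    return generate_survey(three_country_config)


def tiny_frame():
    """Four children, two clusters, one covariate - fully hand-checkable."""
    return pd.DataFrame(
        {
            "country": ["X", "X", "X", "X"],
            "cluster_id": ["c1", "c1", "c2", "c2"],
            "rural": [1, 1, 0, 0],
            "weight": [1.0, 1.0, 1.0, 1.0],
            "outcome": [1, 0, 0, 1],
            "x1": [1, 0, 1, 0],
        }
    )


@pytest.fixture
def tiny_dataset():
    return SurveyDataset(frame=tiny_frame(), provenance="test")
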