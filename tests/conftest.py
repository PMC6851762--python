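"""Shared fixtures: the toy study (hierarchy, covariates, panel, design).

Everything is generated programmatically at module scope so the expensive
pieces are built once per session.
"""

import numpy as np
import pandas as pd
import pytest

from fire_extremes.design import build_design_matrix, fit_spline_specs
from fire_extremes.hierarchy import generate_hierarchy
from fire_extremes.preprocess import (
    COVARIATE_COLUMNS,
    assemble_panel,
    rolling_prior_12_sum,
)
from fire_extremes.synthetic import (
    default_true_parameters,
    simulate_covariates,
    simulate_fires,
)

EMPTY_CATALOG = pd.DataFrame(
    columns=["event_id", "year", "month", "region", "size_ha", "exceedance_ha"]
)


@pytest.fixture(scope="session")
def toy_hierarchy():
    return generate_hierarchy(2, 4, 12, seed=7)


@pytest.fixture(scope="session")
def toy_covariates(toy_hierarchy):
    cov = simulate_covariates(toy_hierarchy, 132, seed=3)
    return rolling_prior_12_sum(cov)


@pytest.fixture(scope="session")
def toy_panel_nofires(toy_hierarchy, toy_covariates):
    return assemble_panel(EMPTY_CATALOG, toy_covariates, toy_hierarchy, split_month=108)


@pytest.fixture(scope="session")
def toy_specs(toy_panel_nofires):
    train = toy_panel_nofires[toy_panel_nofires["split"] == "train"]
    return fit_spline_specs(train, COVARIATE_COLUMNS)


@pytest.fixture(scope="session")
def toy_design(toy_panel_nofires, toy_hierarchy, toy_specs):
    return build_design_matrix(toy_panel_nofires, toy_hierarchy, toy_specs)


@pytest.fixture(scope="session")
def toy_truth(toy_design, toy_hierarchy):
    return default_true_parameters(toy_design, mean_area=float(np.mean(toy_hierarchy.areas())))


@pytest.fixture(scope="session")
def toy_catalog(toy_panel_nofires, toy_design, toy_truth):
    return simulate_fires(toy_panel_nofires, toy_design, toy_truth, seed=11)


@pytest.fixture(scope="session")
def toy_panel(toy_catalog, toy_covariates, toy_hierarchy):
    return assemble_panel(toy_catalog, toy_covariates, toy_hierarchy, split_month=108)
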