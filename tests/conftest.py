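"""Shared fixtures: a small synthetic study and its pipeline products."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import diffpanda as dp
from diffpanda.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def default_params() -> dp.SimulationParams:
    return dp.SimulationParams(seed=7)


@pytest.fixture(scope="session")
def truth(default_params) -> dp.GroundTruth:
    return dp.simulate_truth(default_params)


@pytest.fixture(scope="session")
def study(default_params, truth):
    """One fully simulated study (counts, covariates, priors, drugs)."""
    expr, covariates = dp.simulate_counts(truth, default_params)
    motif, ppi = dp.simulate_priors(truth, default_params)
    db, planted = dp.simulate_drug_db(truth, default_params)
    return {
        "params": default_params,
        "truth": truth,
        "expr": expr,
        "covariates": covariates,
        "motif": motif,
        "ppi": ppi,
        "drug_db": db,
        "planted_reversers": planted,
    }


@pytest.fixture(scope="session")
def group_networks(study):
    """Case and control PANDA networks from the session study."""
    residuals = dp.residualize(
        dp.log_transform(dp.cpm_filter(dp.collapse_duplicates(study["expr"]))),
        study["covariates"],
    )
    nets = {}
    for label in ("case", "control"):
        cols = study["covariates"].index[study["covariates"]["diagnosis"] == label]
        group = ExpressionMatrix(residuals.values[list(cols)], kind="residuals")
        motif_a, ppi_a, coexpr = dp.prepare_inputs(study["motif"], study["ppi"], group)
        nets[label] = dp.panda(motif_a, ppi_a, coexpr)
    return nets


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.poisson(50.0, size=(8, 6)).astype(float),
        index=[f"G{i}" for i in range(8)],
        columns=[f"S{j}" for j in range(6)],
    )
    return ExpressionMatrix(values, kind="counts")


@pytest.fixture
def small_covariates(small_counts) -> pd.DataFrame:
    n = small_counts.n_samples
    return pd.DataFrame(
        {
            "diagnosis": ["case", "control"] * (n // 2),
            "age": [50.0, 60.0, 70.0, 50.0, 60.0, 70.0],
            "batch": ["b1", "b1", "b2", "b2", "b1", "b2"],
        },
        index=small_counts.sample_names,
    )
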