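"""Shared fixtures: one small synthetic world and reduced-MCMC fits,
session-scoped because simulation and sampling dominate test runtime."""

import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from wolfmove.model import ModelSpec, fit_model, subsample_two_thirds
from wolfmove.synthetic import (
    LandscapeConfig,
    SimConfig,
    TruthTable,
    generate_landscape,
    simulate_tracks,
    simulate_zib_data,
)
from wolfmove.validation import recovery_records


@pytest.fixture(scope="session")
def landscape_small():
    return generate_landscape(LandscapeConfig(extent_km=(8.0, 8.0), seed=5))


@pytest.fixture(scope="session")
def sim_tracks(landscape_small):
    truth = TruthTable(
        beta={"settlement_density": -0.4, "tri": -0.3},
        sigma_individual=0.3,
        sigma_cell=0.4,
        sigma_resid=0.6,
        zero_inflation_pi=0.05,
    )
    sim = SimConfig(n_individuals=6, days_per_individual=40, missingness_rate=0.03, seed=6)
    return simulate_tracks(landscape_small, sim, truth)


@pytest.fixture(scope="session")
def gauss_records():
    rec, truth = recovery_records(seed=2, n_individuals=10, days=50)
    rec = subsample_two_thirds(rec, seed=2)
    return rec, truth


@pytest.fixture(scope="session")
def gauss_fit(gauss_records):
    rec, _ = gauss_records
    spec = ModelSpec(response="daily_distance")
    return fit_model(spec, rec, seed=4, n_chains=2, n_iter=900, n_warmup=450, standardize=False)


@pytest.fixture(scope="session")
def zib_fit():
    df = simulate_zib_data(n=600, pi=0.10, beta0=-0.3, beta1=0.8, phi=8.0, seed=8, sigma_individual=0.2)
    df["straightness"] = df["y"]
    df["grid_cell_id"] = "c0"
    df["track_date"] = "2010-06-01"
    df["refuge_dim1"] = df["x"]
    spec = ModelSpec(response="straightness", fixed_terms=("refuge_dim1",), interactions=())
    fit = fit_model(spec, df, seed=9, n_chains=2, n_iter=900, n_warmup=450, standardize=False)
    return fit, df
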