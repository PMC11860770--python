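"""Shared fixtures: a scaled-down simulated panel and pipeline artifacts.

Everything expensive is session-scoped so the suite stays inside a small
runtime budget; tests must not mutate fixture arrays in place.
"""

import numpy as np
import pytest

import airsom as a
from airsom import pmf as pmfmod


def small_config(**overrides):
    """2 simulated years x 28 days x 4 sites, no missingness, 3 episodes."""
    defaults = dict(n_years=2, days_per_year=28, missing_rate=0.0, n_dust_episodes=3)
    defaults.update(overrides)
    return a.SimConfig(**defaults)


def run_pipeline(seed, config=None, grid=(15, 10), epochs=40):
    """Simulate -> autoscale -> SOM -> cluster; returns a dict of artifacts."""
    config = config or small_config()
    panel, truth = a.simulate_panel(config, seed=seed)
    Xs, scaling = a.autoscale(panel.X, panel.variable_names)
    model = a.train_batch_som(
        Xs, a.GridSpec(*grid), a.SomParams(epochs=epochs, seed=0), panel.variable_names
    )
    assignment = a.assign_bmu(model.codebook, Xs)
    clusters = a.select_k(model.codebook, 2, 10)
    return {
        "panel": panel,
        "truth": truth,
        "Xs": Xs,
        "scaling": scaling,
        "model": model,
        "assignment": assignment,
        "clusters": clusters,
    }


@pytest.fixture(scope="session")
def pipeline0():
    return run_pipeline(0)


@pytest.fixture(scope="session")
def mini_panel(pipeline0):
    return pipeline0["panel"]


@pytest.fixture(scope="session")
def mini_model(pipeline0):
    return pipeline0["model"]


@pytest.fixture(scope="session")
def pmf_inputs(pipeline0):
    """Concentration-scale codebook and uncertainty matrix of pipeline0."""
    codebook = pmfmod.concentration_codebook(
        pipeline0["model"].codebook, pipeline0["scaling"]
    )
    umodel = pmfmod.UncertaintyModel.from_data(
        codebook.M, variable_names=codebook.variable_names
    )
    U = pmfmod.build_uncertainties(codebook.M, umodel)
    return codebook, U


@pytest.fixture(scope="session")
def pmf_solution(pmf_inputs):
    codebook, U = pmf_inputs
    return pmfmod.fit_pmf(codebook.M, U, 5, n_starts=8, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
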