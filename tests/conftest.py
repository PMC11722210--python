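"""Shared fixtures.

The full-size scenario pipelines (8,000 cells, GMM estimation for all three
candidates, copula-KDE densities, 200 bootstrap resamples) are expensive, so
they are computed lazily once per session and shared between the acceptance
tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

import tsselect as ts
from tsselect.selection import run_scenario_bootstrap

#: Master seed for the deterministic test runs.
TEST_SEED = 1


@pytest.fixture(scope="session")
def network():
    return ts.build_minimal_nk_network()


@pytest.fixture(scope="session")
def candidates(network):
    return ts.default_candidates(network)


@pytest.fixture(scope="session")
def small_ics(network):
    """A small time-0 population for cheap unit tests (200 cells)."""
    return ts.simulate_initial_conditions(
        200, ts.DEFAULT_LOG_MU, ts.DEFAULT_LOG_SIGMA2, seed=42,
        protein_names=network.species_names,
    )


@pytest.fixture(scope="session")
def tiny_bundle(candidates):
    """A deliberately small scenario bundle for fast pipeline tests."""
    config = ts.SimulatorConfig(scenario="SMALL", n_cells=400, seed=7)
    return ts.generate_scenario(config, candidates)


@pytest.fixture(scope="session")
def scenario_runs():
    """Factory for the full-size study-condition runs, one per scenario.

    Returns (bundle, selection report, bootstrap report with B=200).
    """
    cache: dict[str, tuple] = {}

    def get(scenario: str):
        if scenario not in cache:
            cache[scenario] = run_scenario_bootstrap(scenario, seed=TEST_SEED, B=200)
        return cache[scenario]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
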