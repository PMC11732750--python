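"""Shared fixtures.

Steady-state solves are expensive, so converged states and the scaled
Monte Carlo ensemble are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from sedmoc.core_model import build_model
from sedmoc.ensemble import run_ensemble
from sedmoc.solver import solve_steady_state

# scaled-down study sizes: a 32-cell column for ensemble draws, 200 draws
N_ENSEMBLE = 200
ENSEMBLE_SEED = 11


@pytest.fixture(scope="session")
def canonical_state():
    """Converged canonical mid-shelf column."""
    return solve_steady_state(build_model(), n_cells=45, tol=1e-8)


@pytest.fixture(scope="session")
def no_sorption_state():
    """Canonical column with all kinetic sorption switched off."""
    overrides = {f"sorption.k_sorp_{cls}": 0.0 for cls in ("doc", "gps", "lrdoc")}
    return solve_steady_state(build_model(overrides=overrides),
                              n_cells=45, tol=1e-8)


@pytest.fixture(scope="session")
def scaled_ensemble():
    """Scaled Monte Carlo ensemble over the shipped global ranges."""
    return run_ensemble(n=N_ENSEMBLE, seed=ENSEMBLE_SEED, n_cells=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
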