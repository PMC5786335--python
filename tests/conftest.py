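"""Shared fixtures: solved policies at the standard grid are expensive, so the
full-resolution solutions used across several test modules are session-scoped
and share one set of step operators."""

import numpy as np
import pytest

from riskforage.belief import BeliefGrid
from riskforage.params import ModelParams, SimpleParams
from riskforage.simple import solve_simple
from riskforage.solver import build_operators, value_iteration


@pytest.fixture(scope="session")
def full_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def full_grid_ops(full_params):
    grid = BeliefGrid(full_params.d_beta)
    return grid, build_operators(full_params, grid)


@pytest.fixture(scope="session")
def sol_cd0_non(full_params, full_grid_ops):
    grid, ops = full_grid_ops
    return value_iteration(full_params, interruptible=False, grid=grid, operators=ops)


@pytest.fixture(scope="session")
def sol_cd0_int(full_params, full_grid_ops):
    grid, ops = full_grid_ops
    return value_iteration(full_params, interruptible=True, grid=grid, operators=ops)


@pytest.fixture(scope="session")
def sol_cd001_int(full_params, full_grid_ops, sol_cd0_int):
    grid, ops = full_grid_ops
    return value_iteration(
        full_params.with_(c_d=0.01), interruptible=True, grid=grid, operators=ops,
        v0=sol_cd0_int.V,
    )


@pytest.fixture(scope="session")
def coarse_params() -> ModelParams:
    """Miniature model for oracle comparisons: 3x3 belief grid, two durations."""
    return ModelParams(d_beta=0.5, tau_set=(1, 2))


@pytest.fixture(scope="session")
def simple_params() -> SimpleParams:
    return SimpleParams()


@pytest.fixture(scope="session")
def simple_sol_cd0(simple_params):
    return solve_simple(simple_params)
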