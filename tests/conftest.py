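"""Shared fixtures: scenarios and coarse solved fields reused across tests.

Solves are cached at session scope; meshes are deliberately coarse so the
whole suite stays fast while still exercising every code path.
"""

from __future__ import annotations

import numpy as np
import pytest

from woundfield import (
    build_scenario,
    generate_axisymmetric_mesh,
    generate_voxel_grid,
    solve_scenario_mesh,
)


@pytest.fixture(scope="session")
def endo_scenario():
    return build_scenario("endogenous")


@pytest.fixture(scope="session")
def endo_solution(endo_scenario):
    mesh = generate_axisymmetric_mesh(endo_scenario, resolution_mm=0.3)
    return solve_scenario_mesh(mesh)


@pytest.fixture(scope="session")
def geo1_solution():
    mesh = generate_axisymmetric_mesh(build_scenario("geo1"), resolution_mm=0.3)
    return solve_scenario_mesh(mesh)


@pytest.fixture(scope="session")
def geo5_solution():
    grid = generate_voxel_grid(build_scenario("geo5"), h_mm=0.8)
    return solve_scenario_mesh(grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)
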