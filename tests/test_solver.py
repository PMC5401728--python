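"""Conduction solver: exactness on 1-D problems, conservation, determinism."""

import numpy as np
import pytest

from woundfield.discretization import generate_axisymmetric_mesh
from woundfield.scenarios import build_scenario
from woundfield.solver import SolveError, assemble, solve, solve_scenario_mesh
from woundfield.validation import SlabStack, _slab_scenario, analytic_layered_slab

MM = 1e-3


@pytest.fixture(scope="module")
def single_slab_solution():
    stack = SlabStack(((0.08, 3.0e-3),), 0.03)
    sc = _slab_scenario(stack)
    mesh = generate_axisymmetric_mesh(sc, resolution_mm=0.5)
    return stack, mesh, solve_scenario_mesh(mesh)


class TestExactness:
    def test_linear_in_z_reproduced_to_machine_precision(self, single_slab_solution):
        """A single-layer slab's solution is linear in depth; P1 elements
        with centroid-radius quadrature represent it exactly."""
        stack, mesh, sol = single_slab_solution
        z = mesh.nodes[:, 1]
        t = stack.layers[0][1]
        v_exact = stack.delta_V * (1.0 - z / t)
        assert np.max(np.abs(sol.potential - v_exact)) < 1e-12

    def test_two_layer_series_conduction(self):
        stack = SlabStack(((2e-6, 0.014e-3), (0.026, 0.3e-3)), 0.03)
        sc = _slab_scenario(stack)
        mesh = generate_axisymmetric_mesh(sc, resolution_mm=0.2)
        sol = solve_scenario_mesh(mesh)
        exact = analytic_layered_slab(stack)
        from woundfield.postprocess import electric_field

        E = electric_field(sol)
        mag = np.hypot(E[:, 0], E[:, 1])
        for i, e_exact in enumerate(exact["E"]):
            sel = mesh.element_material == i
            assert np.allclose(mag[sel], e_exact, rtol=1e-9)


class TestWellPosedness:
    def test_endogenous_has_internal_dirichlet_at_30mV(self, endo_solution):
        mesh = endo_solution.mesh
        src = [n for n, v in mesh.electrode_potentials.items() if v == 0.03]
        assert len(src) == 1
        z = mesh.nodes[mesh.node_sets[src[0]], 1] / MM
        assert np.allclose(z, 0.314)

    def test_single_potential_is_ill_posed(self, geo1_solution):
        mesh = geo1_solution.mesh
        saved = dict(mesh.electrode_potentials)
        try:
            for k in mesh.electrode_potentials:
                mesh.electrode_potentials[k] = 0.0
            with pytest.raises(SolveError, match="ill-posed"):
                assemble(mesh)
        finally:
            mesh.electrode_potentials.update(saved)

    def test_conflicting_node_potentials_detected(self, geo1_solution):
        mesh = geo1_solution.mesh
        names = list(mesh.electrode_potentials)
        shared = int(mesh.node_sets[names[0]][0])
        sets = dict(mesh.node_sets)
        try:
            mesh.node_sets[names[1]] = np.append(mesh.node_sets[names[1]], shared)
            with pytest.raises(SolveError, match="two distinct"):
                assemble(mesh)
        finally:
            mesh.node_sets.update(sets)


class TestPhysicalInvariants:
    def test_discrete_maximum_principle(self, endo_solution, geo1_solution):
        for sol in (endo_solution, geo1_solution):
            assert sol.potential.min() >= -1e-9
            assert sol.potential.max() <= 0.03 + 1e-9

    @pytest.mark.parametrize("fixture", ["endo_solution", "geo1_solution", "geo5_solution"])
    def test_global_current_conservation(self, fixture, request):
        """Current out of the source equals current into the ground to 0.1%."""
        sol = request.getfixturevalue(fixture)
        currents = sol.patch_currents
        total = sum(currents.values())
        scale = max(abs(v) for v in currents.values())
        assert abs(total) <= 1e-3 * scale

    def test_linearity_in_applied_potential(self):
        sc1 = build_scenario("geo2")
        sc2 = build_scenario("geo2", {"potential_mV": 60.0})
        m1 = generate_axisymmetric_mesh(sc1, resolution_mm=0.4)
        m2 = generate_axisymmetric_mesh(sc2, resolution_mm=0.4)
        s1 = solve_scenario_mesh(m1)
        s2 = solve_scenario_mesh(m2)
        assert np.allclose(s2.potential, 2.0 * s1.potential, atol=1e-12)

    def test_deterministic_resolve(self, geo1_solution):
        sol2 = solve_scenario_mesh(geo1_solution.mesh)
        assert np.array_equal(sol2.potential, geo1_solution.potential)

    def test_residual_reported(self, endo_solution):
        assert endo_solution.residual_norm < 1e-10
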