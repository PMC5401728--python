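"""Derived quantities: fields, profiles, Joule densities, loop topology."""

import numpy as np
import pytest

from woundfield.discretization import generate_axisymmetric_mesh
from woundfield.geometry import RegionLabel, SKIN_LAYER_LABELS
from woundfield.postprocess import (
    classify_current_loop,
    compute_metrics,
    electric_field,
    layer_joule_density,
    max_field_near_wound,
    sample_line_profile,
    surface_power_density,
    total_joule_power,
)
from woundfield.scenarios import build_scenario
from woundfield.solver import assemble, solve, solve_scenario_mesh
from woundfield.validation import SlabStack, _slab_scenario, analytic_layered_slab


@pytest.fixture(scope="module")
def two_layer():
    stack = SlabStack(((2e-6, 0.014e-3), (0.026, 0.3e-3)), 0.03)
    sc = _slab_scenario(stack)
    mesh = generate_axisymmetric_mesh(sc, resolution_mm=0.25)
    return stack, solve_scenario_mesh(mesh)


class TestElectricField:
    def test_linear_potential_gives_constant_vertical_field(self):
        stack = SlabStack(((0.5, 2.0e-3),), 0.01)
        sc = _slab_scenario(stack)
        mesh = generate_axisymmetric_mesh(sc, resolution_mm=0.5)
        sol = solve_scenario_mesh(mesh)
        E = electric_field(sol)
        # V decreases with depth at 5 V/m; E = -grad V points downward
        # (z increases downward, so E_z = +5)
        assert np.allclose(E[:, 0], 0.0, atol=1e-9)
        assert np.allclose(E[:, 1], 5.0, rtol=1e-9)

    def test_field_ratio_is_inverse_conductivity_ratio(self, two_layer):
        stack, sol = two_layer
        E = electric_field(sol)
        mag = np.hypot(E[:, 0], E[:, 1])
        mesh = sol.mesh
        e_sc = mag[mesh.element_material == 0].mean()
        e_ep = mag[mesh.element_material == 1].mean()
        assert e_sc / e_ep == pytest.approx(0.026 / 2e-6, rel=1e-9)  # 13000

    def test_endogenous_field_concentrates_at_wound_edge(self, endo_solution):
        profile = sample_line_profile(endo_solution)
        sel_far = (profile.x_mm < 4) & profile.in_tissue
        sel_near = (np.abs(profile.x_mm - 12) < 0.5) & profile.in_tissue
        assert profile.E_mV_per_mm[sel_near].max() > 30 * profile.E_mV_per_mm[sel_far].max()


class TestProfiles:
    def test_symmetry_about_the_axis(self, geo1_solution):
        p = sample_line_profile(geo1_solution, n_points=201)
        assert np.allclose(p.E_mV_per_mm, p.E_mV_per_mm[::-1], rtol=1e-12)

    def test_peak_adjacent_to_wound_edge(self, endo_solution):
        p = sample_line_profile(endo_solution)
        _, x = max_field_near_wound(p)
        assert min(abs(x - 8.0), abs(x - 12.0)) <= 1.0

    def test_depth_outside_skin_rejected(self, endo_solution):
        with pytest.raises(ValueError):
            sample_line_profile(endo_solution, z_mm=9.0)

    def test_cavity_points_flagged(self, endo_solution):
        p = sample_line_profile(endo_solution)
        inside = np.abs(p.x_mm - 10) < 1.5  # well inside the wound mouth
        assert not p.in_tissue[inside].any()

    def test_zero_field_for_equal_electrode_potentials(self):
        sc = build_scenario("geo1")
        mesh = generate_axisymmetric_mesh(sc, resolution_mm=0.4)
        dirichlet = {}
        for name in mesh.electrode_potentials:
            for i in mesh.node_sets[name]:
                dirichlet[int(i)] = 0.03
        sol = solve(assemble(mesh, dirichlet=dirichlet))
        p = sample_line_profile(sol)
        val, _ = max_field_near_wound(p)
        assert val == pytest.approx(0.0, abs=1e-7)


class TestJouleDissipation:
    def test_uniform_slab_density_is_sigma_e_squared(self):
        stack = SlabStack(((0.08, 3.0e-3),), 0.03)
        sol = solve_scenario_mesh(
            generate_axisymmetric_mesh(_slab_scenario(stack), resolution_mm=0.5)
        )
        exact = analytic_layered_slab(stack)
        q = layer_joule_density(sol, SKIN_LAYER_LABELS[0])
        assert q == pytest.approx(exact["Q"][0], rel=1e-9)

    def test_energy_balance_exact_for_fem(self, endo_solution, geo1_solution):
        """Sum of sigma|E|^2 over the mesh equals electrode power: the
        element-constant field makes the identity exact."""
        for sol in (endo_solution, geo1_solution):
            assert total_joule_power(sol) == pytest.approx(sol.total_power, rel=1e-9)

    def test_non_layer_rejected(self, endo_solution):
        with pytest.raises(ValueError):
            layer_joule_density(endo_solution, RegionLabel.bath)

    @pytest.mark.parametrize(
        "q, t_mm, expected",
        [(10.0, 0.014, 1.4e-5), (0.0, 5.0, 0.0), (8.05, 0.014, 1.127e-5)],
    )
    def test_surface_power_conversion(self, q, t_mm, expected):
        assert surface_power_density(q, t_mm) == pytest.approx(expected, rel=1e-9)

    def test_surface_power_linearity(self, rng):
        q = rng.uniform(0, 100)
        t = rng.uniform(0.01, 5)
        a = rng.uniform(0.1, 10)
        assert surface_power_density(a * q, t) == pytest.approx(
            a * surface_power_density(q, t)
        )
        assert surface_power_density(q, a * t) == pytest.approx(
            a * surface_power_density(q, t)
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            surface_power_density(-1.0, 1.0)
        with pytest.raises(ValueError):
            surface_power_density(1.0, 0.0)


class TestCurrentLoops:
    def test_endogenous_is_the_two_loop_reference(self, endo_solution):
        pattern, matches = classify_current_loop(endo_solution)
        assert pattern == "two_loop_endogenous_like"
        assert matches

    def test_geo1_matches_endogenous_orientation(self, geo1_solution):
        pattern, matches = classify_current_loop(geo1_solution)
        assert pattern == "two_loop_endogenous_like"
        assert matches

    def test_geo5_is_a_single_transverse_loop(self, geo5_solution):
        pattern, matches = classify_current_loop(geo5_solution)
        assert pattern == "single_loop"
        assert not matches


class TestMetricsReport:
    def test_report_schema_and_consistency(self, geo1_solution):
        rep = compute_metrics(geo1_solution)
        assert rep.scenario_name == "geo1"
        assert set(rep.joule_density_W_per_m3) == {
            "stratum corneum", "epidermis", "dermis", "subcutis",
        }
        for (name, t) in zip(
            rep.joule_density_W_per_m3, (0.014, 0.3, 2.2, 3.0)
        ):
            assert rep.surface_power_mW_per_cm2[name] == pytest.approx(
                surface_power_density(rep.joule_density_W_per_m3[name], t)
            )
        assert min(abs(rep.peak_x_mm - 8), abs(rep.peak_x_mm - 12)) <= 1.0
        s = rep.to_series()
        assert "max_EF_mV_per_mm" in s.index
        assert "Q_stratum_corneum_W_per_m3" in s.index
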