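"""Independent oracles and convergence harnesses for the conduction solver.

The layered-slab closed form is the primary oracle: for plane-parallel
layers carrying a potential difference ΔV in series, the current density is
J = ΔV / Σ(tᵢ/σᵢ), each layer's field Eᵢ = J/σᵢ and its dissipation density
Qᵢ = σᵢEᵢ².  A degenerate scenario (no wound, full-surface electrodes)
reduces both discretizations to 1-D conduction, which they represent
exactly, so agreement to near machine precision certifies the assembly and
solve paths before any comparison with reported simulation values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretization import (
    generate_axisymmetric_mesh,
    generate_voxel_grid,
)
from .geometry import BathSpec, SKIN_LAYER_LABELS
from .postprocess import (
    electric_field,
    layer_joule_density,
    max_field_near_wound,
    sample_line_profile,
)
from .scenarios import (
    ElectrodePatch,
    LayerStack,
    Material,
    ScenarioConfig,
    build_scenario,
    default_layer_stack,
)
from .solver import assemble, solve, solve_scenario_mesh

__all__ = [
    "SlabStack",
    "analytic_layered_slab",
    "slab_equivalence_test",
    "manufactured_convergence",
    "convergence_study",
    "run_validation_suite",
]


@dataclass(frozen=True)
class SlabStack:
    """Plane-parallel conduction stack: (σ S/m, thickness m) pairs, top
    first, with the potential difference applied across it (volts)."""

    layers: tuple[tuple[float, float], ...]
    delta_V: float

    def __post_init__(self) -> None:
        for s, t in self.layers:
            if s <= 0 or t <= 0:
                raise ValueError("slab layers need positive sigma and thickness")

    @classmethod
    def from_default_skin(cls, delta_V: float = 0.03) -> "SlabStack":
        stack = default_layer_stack()
        return cls(
            tuple((m.sigma, t * 1e-3) for m, t in stack.layers), delta_V
        )


def analytic_layered_slab(stack: SlabStack) -> dict:
    """Series-conduction closed form: current density J (A/m²) and
    per-layer field E (V/m) and dissipation Q (W/m³)."""
    resistance = sum(t / s for s, t in stack.layers)  # ohm * m^2
    J = stack.delta_V / resistance
    E = tuple(J / s for s, _ in stack.layers)
    Q = tuple(s * e * e for (s, _), e in zip(stack.layers, E))
    return {"J": J, "E": E, "Q": Q}


def _slab_scenario(stack: SlabStack, radius_mm: float = 10.0) -> ScenarioConfig:
    mats = tuple(
        Material(f"slab{i}", s, 1.0) for i, (s, _) in enumerate(stack.layers)
    )
    layers = LayerStack(tuple((m, t * 1e3) for m, (_, t) in zip(mats, stack.layers)))
    return ScenarioConfig(
        name="slab",
        layers=layers,
        wound=None,
        cylinder_radius_mm=radius_mm,
        bath=BathSpec(height_mm=0.0, margin_mm=0.0),
        ambient=Material("air", 1e-12, 1.0),
        electrodes=(
            ElectrodePatch("top", 0.0, radius_mm, stack.delta_V * 1e3, name="top"),
            ElectrodePatch(
                "interface", 0.0, radius_mm, 0.0, interface="bottom", name="bottom"
            ),
        ),
    )


def slab_equivalence_test(
    mode: str = "axisymmetric",
    stack: SlabStack | None = None,
    resolution_mm: float = 0.2,
) -> float:
    """Solve the degenerate 1-D slab scenario and return the worst relative
    error of the per-layer mean field against the closed form."""
    stack = stack or SlabStack.from_default_skin()
    sc = _slab_scenario(stack)
    exact = analytic_layered_slab(stack)
    if mode == "axisymmetric":
        mesh = generate_axisymmetric_mesh(sc, resolution_mm=resolution_mm)
        sol = solve_scenario_mesh(mesh)
        E = electric_field(sol)
        mag = np.hypot(E[:, 0], E[:, 1])
        meas = mesh.element_measures
        groups = mesh.element_material
    elif mode == "voxel":
        spacing = {
            f"slab{i}": t * 1e3 / 2 for i, (_, t) in enumerate(stack.layers)
        }
        grid = generate_voxel_grid(sc, h_mm=resolution_mm * 10, anisotropic_z=spacing)
        sol = solve_scenario_mesh(grid)
        E = electric_field(sol)
        mag = np.linalg.norm(E, axis=-1)[grid.active]
        meas = grid.cell_volumes[grid.active]
        groups = grid.cell_material[grid.active]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    worst = 0.0
    for i, e_exact in enumerate(exact["E"]):
        sel = groups == i
        e_mean = float((mag[sel] * meas[sel]).sum() / meas[sel].sum())
        worst = max(worst, abs(e_mean - e_exact) / abs(e_exact))
    return worst


def manufactured_convergence(
    resolutions_mm: tuple[float, ...] = (0.8, 0.4, 0.2),
) -> pd.DataFrame:
    """L2 convergence of the axisymmetric solver on a smooth manufactured
    problem (V = z² on a homogeneous cylinder, matching source term).

    Returns a table of (resolution, L2 error, observed order); linear
    elements should show order ≈ 2.
    """
    sigma = 0.5
    mat = Material("medium", sigma, 1.0)
    sc = ScenarioConfig(
        name="manufactured",
        layers=LayerStack(((mat, 5.0),)),
        wound=None,
        cylinder_radius_mm=5.0,
        bath=BathSpec(0.0, 0.0),
        ambient=Material("air", 1e-12, 1.0),
        electrodes=(
            ElectrodePatch("top", 0.0, 5.0, 1.0, name="a"),
            ElectrodePatch("interface", 0.0, 5.0, 0.0, interface="bottom", name="b"),
        ),
    )

    def v_exact(r, z):
        return z * z

    def source(r, z):  # -div(sigma grad V) = -2 sigma
        return np.full_like(np.asarray(r, dtype=float), -2.0 * sigma)

    rows = []
    for res in resolutions_mm:
        mesh = generate_axisymmetric_mesh(sc, resolution_mm=res, grading=1.0)
        r_n, z_n = mesh.nodes[:, 0], mesh.nodes[:, 1]
        tol = 1e-9
        zmax = z_n.max()
        boundary = (
            (np.abs(z_n) < tol)
            | (np.abs(z_n - zmax) < tol)
            | (np.abs(r_n - r_n.max()) < tol)
        )
        dirichlet = {
            int(i): float(v_exact(r_n[i], z_n[i])) for i in np.flatnonzero(boundary)
        }
        system = assemble(mesh, sc, source=source, dirichlet=dirichlet)
        sol = solve(system)
        cent = mesh.element_centroids
        err = sol.potential[mesh.elements].mean(axis=1) - v_exact(
            cent[:, 0], cent[:, 1]
        )
        l2 = math.sqrt(float((err**2 * mesh.element_measures).sum()))
        rows.append({"resolution_mm": res, "l2_error": l2})
    df = pd.DataFrame(rows)
    order = [np.nan]
    for i in range(1, len(df)):
        h1, h2 = df.resolution_mm[i - 1], df.resolution_mm[i]
        e1, e2 = df.l2_error[i - 1], df.l2_error[i]
        order.append(math.log(e1 / e2) / math.log(h1 / h2))
    df["order"] = order
    return df


def convergence_study(
    scenario_name: str,
    resolutions_mm: tuple[float, ...] = (0.4, 0.2, 0.1),
    grading: float = 2.0,
) -> pd.DataFrame:
    """Solve a scenario on successively finer axisymmetric meshes and report
    the wound-edge field maximum and per-layer dissipation densities with
    their successive relative changes."""
    if len(resolutions_mm) < 3:
        raise ValueError("need at least three resolutions")
    if any(b >= a for a, b in zip(resolutions_mm, resolutions_mm[1:])):
        raise ValueError("resolutions must be strictly decreasing")
    sc = build_scenario(scenario_name)
    rows = []
    for res in resolutions_mm:
        mesh = generate_axisymmetric_mesh(sc, resolution_mm=res, grading=grading)
        sol = solve_scenario_mesh(mesh)
        profile = sample_line_profile(sol)
        max_ef, _ = max_field_near_wound(profile)
        row = {
            "resolution_mm": res,
            "n_elements": mesh.n_elements,
            "max_EF_mV_per_mm": max_ef,
        }
        for i, mat in enumerate(sc.layers.materials):
            row[f"Q_{mat.name.replace(' ', '_')}"] = layer_joule_density(
                sol, SKIN_LAYER_LABELS[i]
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col in ("resolution_mm", "n_elements"):
            continue
        vals = df[col].to_numpy()
        rel = [np.nan]
        for i in range(1, len(vals)):
            rel.append(abs(vals[i] - vals[i - 1]) / max(abs(vals[i]), 1e-300))
        df[f"delta_{col}"] = rel
    return df


def run_validation_suite(resolution_mm: float = 0.2) -> pd.DataFrame:
    """Run all oracles; returns a table of (check, value, threshold, pass)."""
    rows = []
    e_ax = slab_equivalence_test("axisymmetric", resolution_mm=resolution_mm)
    rows.append(("slab_equivalence_axisymmetric", e_ax, 1e-6, e_ax < 1e-6))
    e_vx = slab_equivalence_test("voxel", resolution_mm=resolution_mm)
    rows.append(("slab_equivalence_voxel", e_vx, 1e-6, e_vx < 1e-6))
    conv = manufactured_convergence()
    order = float(conv["order"].iloc[-1])
    rows.append(("manufactured_solution_order", order, 1.8, order >= 1.8))
    return pd.DataFrame(rows, columns=["check", "value", "threshold", "passed"])
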