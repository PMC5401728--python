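"""Derived quantities: field profiles, wound-edge maxima, current-loop
orientation and per-layer Joule dissipation.

The headline outputs of the model are

* the magnitude of E = −∇V sampled along a diameter at mid-epidermis depth
  (the ``x`` axis runs 0–20 mm across the skin cylinder, the wound mouth
  edges sitting at x = 8 and 12 mm for the default 4 mm wound),
* the maximum |E| near the wound edge,
* the orientation of the current loops relative to the endogenous pattern
  (the qualitative criterion for a therapeutic electrode layout), and
* volume-averaged Joule heating densities σ|E|² per skin layer with their
  surface-power safety conversion.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretization import MM, TriMesh, VoxelGrid
from .geometry import RegionLabel, SKIN_LAYER_LABELS
from .solver import FieldSolution

__all__ = [
    "FieldProfile",
    "MetricsReport",
    "electric_field",
    "sample_line_profile",
    "max_field_near_wound",
    "layer_joule_density",
    "surface_power_density",
    "classify_current_loop",
    "compute_metrics",
    "metrics_table",
]

#: Flux magnitudes below this fraction of the largest electrode current are
#: treated as zero when classifying current-loop orientation.
LOOP_SIGN_THRESHOLD = 1e-3

_TISSUE_CODES = {int(l) for l in SKIN_LAYER_LABELS}


# ---------------------------------------------------------------------------
# Electric field


def _fem_field(sol: FieldSolution) -> np.ndarray:
    mesh: TriMesh = sol.mesh
    b, c, area, _ = mesh._geom
    v = sol.potential[mesh.elements]  # (m, 3)
    er = -(v * b).sum(axis=1) / (2.0 * area)
    ez = -(v * c).sum(axis=1) / (2.0 * area)
    return np.stack([er, ez], axis=1)


def _voxel_field(sol: FieldSolution) -> np.ndarray:
    """Flux-based per-cell field recovery.

    The normal current density is continuous across voxel faces, so each
    face's harmonic-mean flux divided by the cell's own σ gives that cell's
    field component at the face; per-cell components average the available
    faces.  This is exact for series conduction and respects the field
    jumps at material interfaces (unlike plain central differences).
    """
    grid: VoxelGrid = sol.mesh
    P = sol.potential_grid()
    sig = grid.cell_sigma
    act = grid.active
    E = np.zeros(grid.shape + (3,))

    # faces severed by electrode planes must not contribute
    severed_cols: dict[int, set] = {}
    for ef in grid.electrode_faces:
        if 0 < ef.k_level < grid.shape[2]:
            severed_cols.setdefault(ef.k_level, set()).update(
                (int(i), int(j)) for i, j in ef.columns
            )

    def _along(arr, ax):
        sh = [1, 1, 1]
        sh[ax] = -1
        return arr.reshape(sh)

    for axis in range(3):
        dw = grid.widths[axis]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        valid = act[sl_lo] & act[sl_hi]
        if axis == 2 and severed_cols:
            for k_level, cols in severed_cols.items():
                for i, j in cols:
                    valid[i, j, k_level - 1] = False
        d1 = np.broadcast_to(_along(0.5 * dw[:-1], axis), valid.shape)
        d2 = np.broadcast_to(_along(0.5 * dw[1:], axis), valid.shape)
        s1, s2 = sig[sl_lo], sig[sl_hi]
        with np.errstate(invalid="ignore"):
            J = np.where(
                valid, (P[sl_lo] - P[sl_hi]) / (d1 / s1 + d2 / s2), 0.0
            )
        acc = np.zeros(grid.shape)
        cnt = np.zeros(grid.shape)
        acc[sl_lo] += np.where(valid, J / s1, 0.0)
        cnt[sl_lo] += valid
        acc[sl_hi] += np.where(valid, J / s2, 0.0)
        cnt[sl_hi] += valid
        if axis == 2:
            dz = grid.widths[2]
            for ef in grid.electrode_faces:
                ii, jj = ef.columns[:, 0], ef.columns[:, 1]
                for k_cell, sign in ((ef.k_level, +1), (ef.k_level - 1, -1)):
                    if k_cell < 0 or k_cell >= grid.shape[2]:
                        continue
                    ok = act[ii, jj, k_cell]
                    e_face = (
                        sign
                        * (ef.potential_V - P[ii, jj, k_cell])
                        / (0.5 * dz[k_cell])
                    )
                    acc[ii[ok], jj[ok], k_cell] += e_face[ok]
                    cnt[ii[ok], jj[ok], k_cell] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            E[..., axis] = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    E[~act] = 0.0
    return E


def electric_field(sol: FieldSolution) -> np.ndarray:
    """Per-element (E_r, E_z) or per-cell (E_x, E_y, E_z) in V/m.

    Triangle meshes: the exact P1 gradient, constant per element (E_theta
    vanishes by axisymmetry).  Voxel grids: flux-based recovery from the
    harmonic-mean face fluxes (see :func:`_voxel_field`).
    """
    cache = getattr(sol, "_field_cache", None)
    if cache is None:
        cache = _fem_field(sol) if sol.axisymmetric else _voxel_field(sol)
        sol._field_cache = cache
    return cache


# ---------------------------------------------------------------------------
# Line profiles


@dataclass
class FieldProfile:
    """|E| along a diameter at fixed depth.

    ``x_mm`` runs across the full diameter (0 at one cylinder edge);
    ``in_tissue`` flags samples inside skin (False in the wound cavity,
    bath, or excised regions, whose |E| is the ambient medium's or zero).
    """

    x_mm: np.ndarray
    E_mV_per_mm: np.ndarray
    in_tissue: np.ndarray
    z_mm: float
    scenario_name: str
    wound_edge_x_mm: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": self.x_mm,
                "E_mV_per_mm": self.E_mV_per_mm,
                "in_tissue": self.in_tissue,
            }
        )


def _default_profile_depth_mm(scenario) -> float:
    """Middle of the epidermis layer (0.164 mm with default thicknesses)."""
    names = [m.name for m in scenario.layers.materials]
    i = names.index("epidermis") if "epidermis" in names else min(1, len(names) - 1)
    ifs = scenario.layers.interfaces_mm
    return 0.5 * (ifs[i] + ifs[i + 1])


def _locate_elements(mesh: TriMesh, r_m: np.ndarray, z_m: np.ndarray) -> np.ndarray:
    import matplotlib.tri as mtri

    finder = getattr(mesh, "_finder", None)
    if finder is None:
        tr = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements)
        finder = tr.get_trifinder()
        mesh._finder = finder
    return np.asarray(finder(r_m, z_m), dtype=np.int64)


def _nodal_region_field(sol: FieldSolution, region: int) -> np.ndarray:
    """Measure-weighted nodal average of the element field, restricted to
    one region (fields are discontinuous across material interfaces, so
    recovery never averages across them)."""
    cache = getattr(sol, "_nodal_field_cache", None)
    if cache is None:
        cache = sol._nodal_field_cache = {}
    if region not in cache:
        mesh: TriMesh = sol.mesh
        E = electric_field(sol)
        sel = mesh.element_region == region
        w = mesh.element_measures[sel]
        tri = mesh.elements[sel]
        acc = np.zeros((mesh.n_nodes, 2))
        wsum = np.zeros(mesh.n_nodes)
        for k in range(3):
            np.add.at(acc, tri[:, k], E[sel] * w[:, None])
            np.add.at(wsum, tri[:, k], w)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc /= wsum[:, None]
        cache[region] = np.nan_to_num(acc)
    return cache[region]


def _sample_field_at(sol: FieldSolution, r_mm, z_mm, y_mm=0.0, recovery="element"):
    """(|E| V/m, region code, found mask) at sample points.

    For axisymmetric solutions the points are (r, z); for voxel solutions
    they are placed at (x=r, y=y_mm, z) — callers handle signs.
    ``recovery="nodal"`` (triangle meshes) interpolates the region-restricted
    nodal-averaged field instead of the raw element-constant one.
    """
    r = np.atleast_1d(np.asarray(r_mm, dtype=float))
    z = np.atleast_1d(np.asarray(z_mm, dtype=float))
    r, z = np.broadcast_arrays(r, z)
    if sol.axisymmetric:
        mesh: TriMesh = sol.mesh
        r_m, z_m = np.abs(r) * MM, z * MM
        els = _locate_elements(mesh, r_m, z_m)
        found = els >= 0
        E = electric_field(sol)
        mag = np.zeros(r.shape)
        reg = np.full(r.shape, int(RegionLabel.outside))
        reg[found] = sol.mesh.element_region[els[found]]
        if recovery == "element":
            mag[found] = np.hypot(E[els[found], 0], E[els[found], 1])
        else:
            b, c, area, _ = mesh._geom
            fl = np.flatnonzero(found.ravel())
            e_fl = els.ravel()[fl]
            tri = mesh.elements[e_fl]
            p = mesh.nodes[tri]  # (k, 3, 2)
            # barycentric shape values at the sample points
            a_i = (
                p[:, [1, 2, 0], 0] * p[:, [2, 0, 1], 1]
                - p[:, [2, 0, 1], 0] * p[:, [1, 2, 0], 1]
            )
            pr = r_m.ravel()[fl][:, None]
            pz = z_m.ravel()[fl][:, None]
            N = (a_i + b[e_fl] * pr + c[e_fl] * pz) / (2.0 * area[e_fl][:, None])
            vals = np.zeros((len(fl), 2))
            regs = mesh.element_region[e_fl]
            for rg in np.unique(regs):
                nf = _nodal_region_field(sol, int(rg))
                selr = regs == rg
                vals[selr] = np.einsum("kn,knd->kd", N[selr], nf[tri[selr]])
            mag.ravel()[fl] = np.hypot(vals[:, 0], vals[:, 1])
        return mag, reg, found
    grid: VoxelGrid = sol.mesh
    xs = r * MM
    ys = np.full(r.shape, y_mm * MM)
    zs = z * MM
    i = np.searchsorted(grid.x_edges, xs, side="right") - 1
    j = np.searchsorted(grid.y_edges, ys, side="right") - 1
    k = np.searchsorted(grid.z_edges, zs, side="right") - 1
    nx, ny, nz = grid.shape
    inside = (i >= 0) & (i < nx) & (j >= 0) & (j < ny) & (k >= 0) & (k < nz)
    i, j, k = np.clip(i, 0, nx - 1), np.clip(j, 0, ny - 1), np.clip(k, 0, nz - 1)
    found = inside & grid.active[i, j, k]
    E = electric_field(sol)
    mag = np.where(found, np.linalg.norm(E[i, j, k], axis=-1), 0.0)
    reg = np.where(found, grid.cell_region[i, j, k], int(RegionLabel.outside))
    return mag, reg, found


def sample_line_profile(
    sol: FieldSolution,
    z_mm: float | None = None,
    n_points: int = 401,
    y_mm: float = 0.0,
    recovery: str = "element",
) -> FieldProfile:
    """Sample |E| along a full diameter at depth ``z_mm`` (default:
    mid-epidermis)."""
    sc = sol.scenario
    if z_mm is None:
        z_mm = _default_profile_depth_mm(sc)
    if not 0.0 <= z_mm <= sc.layers.total_thickness_mm:
        raise ValueError(f"sampling depth {z_mm} mm outside the skin")
    R = sc.cylinder_radius_mm
    x = np.linspace(0.0, 2 * R, n_points)
    r_signed = x - R  # voxel solutions keep the sign; axisymmetric takes |r|
    mag, reg, _found = _sample_field_at(sol, r_signed, z_mm, y_mm=y_mm, recovery=recovery)
    in_tissue = np.isin(reg, list(_TISSUE_CODES))
    w = sc.wound.top_radius_mm if sc.wound is not None else 0.0
    return FieldProfile(
        x_mm=x,
        E_mV_per_mm=mag,  # 1 V/m == 1 mV/mm
        in_tissue=in_tissue,
        z_mm=z_mm,
        scenario_name=sc.name,
        wound_edge_x_mm=(R - w, R + w),
    )


def max_field_near_wound(
    profile: FieldProfile, edge_band_mm: float = 1.0
) -> tuple[float, float]:
    """Maximum tissue-side |E| (mV/mm) within ``edge_band_mm`` of the wound
    edge, with the x position of the maximum."""
    xl, xr = profile.wound_edge_x_mm
    near = (np.abs(profile.x_mm - xl) <= edge_band_mm) | (
        np.abs(profile.x_mm - xr) <= edge_band_mm
    )
    sel = near & profile.in_tissue
    if not sel.any():
        raise ValueError("no tissue sample points within the wound-edge band")
    i = np.argmax(np.where(sel, profile.E_mV_per_mm, -np.inf))
    return float(profile.E_mV_per_mm[i]), float(profile.x_mm[i])


# ---------------------------------------------------------------------------
# Joule dissipation


def layer_joule_density(sol: FieldSolution, layer: RegionLabel) -> float:
    """Volume-averaged Joule dissipation ∫σ|E|²dV / V_layer in W/m³.

    The wound cavity is not part of any layer's volume: the average runs
    over tissue only.
    """
    if layer not in SKIN_LAYER_LABELS:
        raise ValueError(f"{layer!r} is not a skin layer")
    E = electric_field(sol)
    if sol.axisymmetric:
        mesh: TriMesh = sol.mesh
        sel = mesh.element_region == int(layer)
        if not sel.any():
            raise ValueError(f"mesh contains no {RegionLabel(layer).name} elements")
        q = mesh.element_sigma[sel] * (E[sel] ** 2).sum(axis=1)
        meas = mesh.element_measures[sel]
        return float((q * meas).sum() / meas.sum())
    grid: VoxelGrid = sol.mesh
    sel = (grid.cell_region == int(layer)) & grid.active
    if not sel.any():
        raise ValueError(f"grid contains no {RegionLabel(layer).name} cells")
    q = grid.cell_sigma[sel] * (E[sel] ** 2).sum(axis=-1)
    vol = grid.cell_volumes[sel]
    return float((q * vol).sum() / vol.sum())


def total_joule_power(sol: FieldSolution) -> float:
    """∫σ|E|²dV over the whole conductive domain (watts)."""
    E = electric_field(sol)
    if sol.axisymmetric:
        mesh: TriMesh = sol.mesh
        return float(
            (mesh.element_sigma * (E**2).sum(axis=1) * mesh.element_measures).sum()
        )
    grid: VoxelGrid = sol.mesh
    q = grid.cell_sigma * (E**2).sum(axis=-1)
    return float((q * grid.cell_volumes)[grid.active].sum())


def surface_power_density(q_W_per_m3: float, thickness_mm: float) -> float:
    """Convert a volumetric dissipation density to the surface power density
    absorbed by a layer of the given thickness, in mW/cm².

    q [W/m³] × t [m] gives W/m²; 1 W/m² = 0.1 mW/cm².
    """
    if q_W_per_m3 < 0:
        raise ValueError("dissipation density cannot be negative")
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    return q_W_per_m3 * thickness_mm * 1e-4


# ---------------------------------------------------------------------------
# Current-loop orientation


def _sign_with_threshold(value: float, scale: float) -> int:
    if abs(value) < LOOP_SIGN_THRESHOLD * scale:
        return 0
    return 1 if value > 0 else -1


def _fem_flow_integrals(sol: FieldSolution) -> tuple[float, float, float]:
    sc = sol.scenario
    mesh: TriMesh = sol.mesh
    E = electric_field(sol)
    wound = sc.wound

    mouth = 0.0
    if wound is not None:
        z_s = min(0.25, 0.25 * wound.depth_mm)
        r_max = wound.top_radius_mm * (1 - z_s / wound.depth_mm)
        r = np.linspace(0.0, 0.98 * r_max, 64)
        els = _locate_elements(mesh, r * MM, np.full_like(r, z_s) * MM)
        jz = np.zeros_like(r)
        ok = els >= 0
        jz[ok] = mesh.element_sigma[els[ok]] * E[els[ok], 1]
        mouth = float(np.trapezoid(jz * 2 * math.pi * r * MM, r * MM))

    # radial current through a cylindrical strip just outside the wound,
    # spanning the epidermis + dermis depth band
    r_s = (wound.top_radius_mm + 1.0) if wound is not None else 3.0
    ifs = sc.layers.interfaces_mm
    z_lo = ifs[1] if len(ifs) > 2 else ifs[0]
    z_hi = ifs[3] if len(ifs) > 3 else ifs[-1]
    z = np.linspace(z_lo + 1e-6, z_hi - 1e-6, 64)
    els = _locate_elements(mesh, np.full_like(z, r_s) * MM, z * MM)
    jr = np.zeros_like(z)
    ok = els >= 0
    jr[ok] = mesh.element_sigma[els[ok]] * E[els[ok], 0]
    side = float(np.trapezoid(jr * 2 * math.pi * r_s * MM, z * MM))
    # axisymmetry: both sides behave identically; each carries half
    return mouth, 0.5 * side, 0.5 * side


def _voxel_flow_integrals(sol: FieldSolution) -> tuple[float, float, float]:
    sc = sol.scenario
    grid: VoxelGrid = sol.mesh
    E = electric_field(sol)
    xc, yc, zc = grid.centers
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    Rc = np.hypot(X, Y)
    wound = sc.wound

    mouth = 0.0
    if wound is not None:
        ks = np.flatnonzero(zc > 0)
        if len(ks):
            k = ks[0]
            zk = zc[k] / MM
            r_w = wound.top_radius_mm * max(0.0, 1 - zk / wound.depth_mm)
            sel = (
                grid.active[:, :, k]
                & (grid.cell_region[:, :, k] == int(RegionLabel.wound_cavity))
                & (Rc[:, :, k] <= r_w * MM)
            )
            dx, dy, _ = grid.widths
            A = dx[:, None] * dy[None, :]
            jz = grid.cell_sigma[:, :, k] * E[:, :, k, 2]
            mouth = float((jz * A)[sel].sum())

    r_s = ((wound.top_radius_mm + 1.0) if wound is not None else 3.0) * MM
    ifs = sc.layers.interfaces_mm
    z_lo = (ifs[1] if len(ifs) > 2 else ifs[0]) * MM
    z_hi = (ifs[3] if len(ifs) > 3 else ifs[-1]) * MM
    h = float(np.diff(grid.x_edges).mean())
    band = grid.active & (np.abs(Rc - r_s) <= h) & (Z > z_lo) & (Z < z_hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        jr = grid.cell_sigma * (
            E[..., 0] * X / np.maximum(Rc, 1e-12) + E[..., 1] * Y / np.maximum(Rc, 1e-12)
        )
    vol = grid.cell_volumes
    plus = band & (X > 0)
    minus = band & (X < 0)
    s_plus = float((jr * vol)[plus].sum() / (2 * h))
    s_minus = float((jr * vol)[minus].sum() / (2 * h))
    return mouth, s_plus, s_minus


@functools.lru_cache(maxsize=1)
def _endogenous_reference_signs() -> tuple[int, int]:
    """Flow signs (mouth, in-tissue radial) of the endogenous field, from a
    coarse dedicated solve; cached for the process lifetime."""
    from .discretization import generate_axisymmetric_mesh
    from .scenarios import build_scenario
    from .solver import solve_scenario_mesh

    sc = build_scenario("endogenous")
    sol = solve_scenario_mesh(generate_axisymmetric_mesh(sc, resolution_mm=0.3))
    mouth, side, _ = _fem_flow_integrals(sol)
    scale = max(abs(v) for v in sol.patch_currents.values())
    return (
        _sign_with_threshold(mouth, scale),
        _sign_with_threshold(side, scale),
    )


def classify_current_loop(
    sol: FieldSolution, reference_signs: tuple[int, int] | None = None
) -> tuple[str, bool]:
    """Classify the current-loop topology of a solved scenario.

    Measures (i) the net vertical current through the wound mouth and
    (ii) the net radial current in the epidermis+dermis band just outside
    the wound on two opposite sides.  Returns ``(pattern, matches)`` where
    pattern is ``"two_loop_endogenous_like"`` (side signs symmetric and
    matching the endogenous reference), ``"single_loop"`` (side signs
    antisymmetric: current traverses the wound laterally) or ``"other"``;
    ``matches`` reports whether the in-tissue flow direction equals the
    endogenous one on both sides.
    """
    if sol.potential is None:
        raise ValueError("unsolved input")
    if sol.axisymmetric:
        mouth, p, m = _fem_flow_integrals(sol)
    else:
        mouth, p, m = _voxel_flow_integrals(sol)
    scale = max(abs(v) for v in sol.patch_currents.values())
    s_mouth = _sign_with_threshold(mouth, scale)
    s_p = _sign_with_threshold(p, scale)
    s_m = _sign_with_threshold(m, scale)
    ref_mouth, ref_side = reference_signs or _endogenous_reference_signs()

    matches = s_p == ref_side and s_m == ref_side
    if s_p != 0 and s_p == s_m and matches:
        pattern = "two_loop_endogenous_like"
    elif s_p != 0 and s_p == -s_m:
        pattern = "single_loop"
    else:
        pattern = "other"
    return pattern, matches


# ---------------------------------------------------------------------------
# Metrics report


def _column_key(material_name: str) -> str:
    return material_name.replace(" ", "_")


@dataclass
class MetricsReport:
    """Summary metrics of one solved scenario (the headline outputs)."""

    scenario_name: str
    max_EF_mV_per_mm: float
    peak_x_mm: float
    loop_pattern: str
    direction_matches_endogenous: bool
    joule_density_W_per_m3: dict[str, float]
    surface_power_mW_per_cm2: dict[str, float]
    profile_depth_mm: float = 0.0

    def to_series(self) -> pd.Series:
        data = {
            "scenario": self.scenario_name,
            "max_EF_mV_per_mm": self.max_EF_mV_per_mm,
            "peak_x_mm": self.peak_x_mm,
            "loop_pattern": self.loop_pattern,
            "direction_matches_endogenous": self.direction_matches_endogenous,
        }
        for k, v in self.joule_density_W_per_m3.items():
            data[f"Q_{_column_key(k)}_W_per_m3"] = v
        for k, v in self.surface_power_mW_per_cm2.items():
            data[f"P_{_column_key(k)}_mW_per_cm2"] = v
        return pd.Series(data)


def compute_metrics(
    sol: FieldSolution,
    n_points: int = 401,
    edge_band_mm: float = 1.0,
    classify_loop: bool = True,
    recovery: str = "element",
) -> MetricsReport:
    """All paper-facing metrics of a solved scenario in one report."""
    if not sol.axisymmetric:
        recovery = "element"
    profile = sample_line_profile(sol, n_points=n_points, recovery=recovery)
    max_ef, x_peak = max_field_near_wound(profile, edge_band_mm)
    if classify_loop:
        pattern, matches = classify_current_loop(sol)
    else:
        pattern, matches = "not_classified", False
    q: dict[str, float] = {}
    p: dict[str, float] = {}
    layers = sol.scenario.layers
    for i, (mat, t) in enumerate(layers.layers):
        if i >= len(SKIN_LAYER_LABELS):
            break
        qi = layer_joule_density(sol, SKIN_LAYER_LABELS[i])
        q[mat.name] = qi
        p[mat.name] = surface_power_density(qi, t)
    return MetricsReport(
        scenario_name=sol.scenario.name,
        max_EF_mV_per_mm=max_ef,
        peak_x_mm=x_peak,
        loop_pattern=pattern,
        direction_matches_endogenous=matches,
        joule_density_W_per_m3=q,
        surface_power_mW_per_cm2=p,
        profile_depth_mm=profile.z_mm,
    )


def metrics_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """One row per scenario, columns matching the summary-table layout."""
    return pd.DataFrame([r.to_series() for r in reports]).reset_index(drop=True)
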