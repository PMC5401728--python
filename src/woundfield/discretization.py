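"""Interface-conforming discretizations of the wound model.

Two mesh families:

* :func:`generate_axisymmetric_mesh` — a mapped structured triangulation of
  the ``(r, z)`` half-plane for axisymmetric scenarios.  Every material
  interface (layer boundaries, the wound-cone line, electrode patch edges)
  is a grid line, so no element straddles an interface.  The radial grid is
  mapped so one column of nodes follows the slanted cone; cells inside the
  cone collapse cleanly at the apex and are merged away.
* :func:`generate_voxel_grid` — a Cartesian cell-centred grid for the
  non-axisymmetric sector-electrode scenarios.  The wound cone is
  staircase-approximated; layer interfaces are exact grid planes because the
  vertical spacing is chosen per layer.

Internally everything is in SI (metres); scenario interfaces are in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import geometry
from .geometry import RegionLabel, SKIN_LAYER_LABELS
from .scenarios import Material, ScenarioConfig, ScenarioError

__all__ = ["TriMesh", "VoxelGrid", "MeshError", "generate_axisymmetric_mesh", "generate_voxel_grid"]

MM = 1e-3
_TOL = 1e-9  # metres; node-on-plane tolerance


class MeshError(ValueError):
    """Mesh generation failed or a mesh is invalid for the request."""


# ---------------------------------------------------------------------------
# Axisymmetric triangle mesh


@dataclass
class TriMesh:
    """Axisymmetric triangulation of the (r, z) half-plane.

    ``nodes`` are (n, 2) coordinates in metres (r, z with z downward);
    ``elements`` are (m, 3) node triples; per-element material and region
    tags; ``node_sets`` name electrode patches and material interfaces.
    ``electrode_potentials`` maps electrode set names to volts.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_material: np.ndarray
    materials: list[Material]
    element_region: np.ndarray
    node_sets: dict[str, np.ndarray]
    electrode_potentials: dict[str, float]
    scenario: ScenarioConfig

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @cached_property
    def element_sigma(self) -> np.ndarray:
        sig = np.array([m.sigma for m in self.materials])
        return sig[self.element_material]

    @cached_property
    def _geom(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(b, c, area, rbar): P1 shape-gradient coefficients per element."""
        p = self.nodes[self.elements]  # (m, 3, 2)
        r, z = p[..., 0], p[..., 1]
        b = np.stack([z[:, 1] - z[:, 2], z[:, 2] - z[:, 0], z[:, 0] - z[:, 1]], axis=1)
        c = np.stack([r[:, 2] - r[:, 1], r[:, 0] - r[:, 2], r[:, 1] - r[:, 0]], axis=1)
        area = 0.5 * (
            (r[:, 1] - r[:, 0]) * (z[:, 2] - z[:, 0])
            - (r[:, 2] - r[:, 0]) * (z[:, 1] - z[:, 0])
        )
        rbar = r.mean(axis=1)
        return b, c, area, rbar

    @property
    def element_areas(self) -> np.ndarray:
        return self._geom[2]

    @property
    def element_rbar(self) -> np.ndarray:
        return self._geom[3]

    @cached_property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    @cached_property
    def element_measures(self) -> np.ndarray:
        """Solid-of-revolution volume of each element: 2*pi*rbar*A (m^3).

        Exact for linear triangles since the centroid radius integrates r
        over the triangle exactly.
        """
        _, _, area, rbar = self._geom
        return 2.0 * math.pi * rbar * area

    def validate(self) -> None:
        if np.any(self.element_areas <= 0):
            raise MeshError("non-positively-oriented or degenerate element")
        if np.any(self.nodes[:, 0] < -_TOL):
            raise MeshError("node at negative radius")
        n = self.n_nodes
        for name, idx in self.node_sets.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise MeshError(f"node set {name!r} references invalid nodes")
        seen: dict[int, float] = {}
        for name, v in self.electrode_potentials.items():
            for i in self.node_sets[name]:
                if i in seen and seen[i] != v:
                    raise MeshError(f"node {i} assigned two distinct potentials")
                seen[i] = v


def _layer_rows(t_mm: float, resolution_mm: float, min_rows: int) -> int:
    return max(min_rows, int(math.ceil(t_mm / resolution_mm)))


def _graded_unit(n: int, power: float, cluster: str) -> np.ndarray:
    """n+1 points on [0, 1]; spacing shrinks toward the clustered end."""
    u = np.linspace(0.0, 1.0, n + 1)
    if power == 1.0 or cluster == "none":
        return u
    if cluster == "start":
        return u**power
    if cluster == "end":
        return 1.0 - (1.0 - u) ** power
    raise ValueError(cluster)


def _insert_sorted(base: np.ndarray, extra: list[float], tol: float = 1e-10) -> np.ndarray:
    vals = np.concatenate([base, np.asarray(extra, dtype=float)])
    vals.sort()
    keep = np.concatenate([[True], np.diff(vals) > tol])
    return vals[keep]


def _required_fractions(
    scenario: ScenarioConfig, R_dom: float
) -> tuple[list[float], list[float], list[float]]:
    """Map electrode-patch edges to required grid lines.

    Returns (inside-cone radial fractions, outside-cone radial fractions,
    extra z levels in mm).  Radii on the top surface map through the
    wound-mouth radius; radii on an internal interface through the cone
    radius at that depth.  Wound-bed patch edges pin z rows where the cone
    reaches the projected radius.
    """
    xi_extra: list[float] = []
    eta_extra: list[float] = []
    z_extra: list[float] = []
    wound = scenario.wound
    for p in scenario.electrodes:
        if p.placement == "wound_bed":
            assert wound is not None
            for rb in (p.r_in_mm, p.r_out_mm):
                if 1e-12 < rb < wound.top_radius_mm - 1e-12:
                    z_extra.append(wound.depth_mm * (1.0 - rb / wound.top_radius_mm))
            continue
        if p.placement == "interface" or (p.placement == "sector" and p.interface):
            z_p = scenario.layers.interface_depth_mm(p.interface)
        else:
            z_p = 0.0
        w = float(geometry._cone_radius_clamped(np.asarray(z_p), wound))
        for rb in (p.r_in_mm, p.r_out_mm):
            if rb <= 1e-12 or rb >= R_dom - 1e-12 or abs(rb - w) < 1e-9:
                continue
            if rb < w:
                xi_extra.append(rb / w)
            else:
                eta_extra.append((rb - w) / (R_dom - w))
    return xi_extra, eta_extra, z_extra


def generate_axisymmetric_mesh(
    scenario: ScenarioConfig,
    resolution_mm: float = 0.1,
    grading: float = 2.0,
    include_nonconductive: bool = False,
) -> TriMesh:
    """Structured, interface-conforming triangulation for an axisymmetric
    scenario.

    ``resolution_mm`` is the target element size; ``grading`` (>= 1)
    geometrically concentrates radial lines toward the wound edge.  Elements
    of insulating media (air ambient) are excised unless
    ``include_nonconductive``; the excised boundary then carries the natural
    zero-flux condition.
    """
    if not scenario.axisymmetric:
        raise MeshError(
            "scenario has angular-sector electrodes; use generate_voxel_grid"
        )
    if resolution_mm <= 0:
        raise MeshError("resolution must be positive")
    layers = scenario.layers
    thicknesses = layers.thicknesses_mm
    t_min = min(thicknesses)
    if resolution_mm > 50 * t_min and t_min < 0.05:
        # thin stratum corneum must still receive >= 2 rows of sane aspect
        raise MeshError(
            f"resolution {resolution_mm} mm too coarse for a {t_min} mm layer"
        )

    R = scenario.cylinder_radius_mm
    R_dom = R + scenario.bath.margin_mm
    gen_bath = scenario.bath.height_mm > 0 and (
        include_nonconductive or not scenario.ambient.insulating
    )

    # --- z levels: per-region rows, layer interfaces exact ---
    z_levels = [np.array([0.0])]
    if gen_bath:
        n = _layer_rows(scenario.bath.height_mm, resolution_mm, 2)
        z_levels.insert(
            0, np.linspace(-scenario.bath.height_mm, 0.0, n + 1)[:-1]
        )
    z0 = 0.0
    for mat, t in layers.layers:
        min_rows = 4 if mat.name == "epidermis" else 2
        n = _layer_rows(t, resolution_mm, min_rows)
        z_levels.append(np.linspace(z0, z0 + t, n + 1)[1:])
        z0 += t
    z_mm = np.concatenate(z_levels)

    # --- radial fractions (inside cone / outside cone) ---
    w0 = scenario.wound.top_radius_mm if scenario.wound is not None else 0.0
    xi_extra, eta_extra, z_extra = _required_fractions(scenario, R_dom)
    if z_extra:
        z_mm = _insert_sorted(z_mm, z_extra)
    if w0 > 0:
        n_in = max(3, int(math.ceil(w0 / resolution_mm)))
        xi = _graded_unit(n_in, grading, "end")  # cluster toward the cone
        xi = _insert_sorted(xi, xi_extra)
    else:
        xi = np.array([1.0])
    n_out = max(4, int(math.ceil((R_dom - w0) / resolution_mm)))
    eta = _graded_unit(n_out, grading, "start")  # cluster toward the wound edge
    if scenario.bath.margin_mm > 0:
        eta_extra.append((R - w0) / (R_dom - w0))
    eta = _insert_sorted(eta, eta_extra)

    # --- mapped node grid: one column follows the cone line ---
    w_of_z = geometry._cone_radius_clamped(z_mm, scenario.wound)
    # above the surface the mouth cylinder continues straight up
    w_of_z = np.where(z_mm < 0, w0, w_of_z)
    r_grid = np.concatenate(
        [
            xi[None, :-1] * w_of_z[:, None],
            w_of_z[:, None] + eta[None, :] * (R_dom - w_of_z[:, None]),
        ],
        axis=1,
    )  # (nrow, ncol)
    nrow, ncol = r_grid.shape
    nodes_mm = np.stack(
        [r_grid, np.broadcast_to(z_mm[:, None], r_grid.shape)], axis=-1
    ).reshape(-1, 2)
    nodes = nodes_mm * MM

    # --- quads -> triangles along the shorter diagonal ---
    ii, jj = np.meshgrid(np.arange(nrow - 1), np.arange(ncol - 1), indexing="ij")
    n00 = (ii * ncol + jj).ravel()
    n01 = n00 + 1
    n10 = n00 + ncol
    n11 = n10 + 1
    d0 = np.linalg.norm(nodes[n00] - nodes[n11], axis=1)
    d1 = np.linalg.norm(nodes[n01] - nodes[n10], axis=1)
    use0 = d0 <= d1
    tri_a = np.where(use0[:, None], np.stack([n00, n01, n11], 1), np.stack([n00, n01, n10], 1))
    tri_b = np.where(use0[:, None], np.stack([n00, n11, n10], 1), np.stack([n01, n11, n10], 1))
    tris = np.concatenate([tri_a, tri_b], axis=0)

    # --- merge duplicate nodes (cone-apex collapse), drop slivers ---
    keys = np.round(nodes / 1e-12).astype(np.int64)
    _, uniq_idx, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    nodes = nodes[uniq_idx]
    tris = inverse[tris]
    distinct = (
        (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
    )
    tris = tris[distinct]
    p = nodes[tris]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    tris = tris[np.abs(area2) > 1e-20]

    # --- material / region tags from centroid classification ---
    cent_mm = nodes[tris].mean(axis=1) / MM
    region = geometry.classify_points(cent_mm[:, 0], cent_mm[:, 1], scenario)
    if np.any(region == int(RegionLabel.outside)):
        raise MeshError("element centroid classified outside the domain")
    materials = list(layers.materials) + [scenario.ambient]
    ambient_idx = len(materials) - 1
    mat_idx = np.full(len(tris), ambient_idx, dtype=np.int64)
    for i in range(layers.n_layers):
        mat_idx[region == int(SKIN_LAYER_LABELS[i])] = i

    if not include_nonconductive:
        keep = np.array([not materials[k].insulating for k in range(len(materials))])[
            mat_idx
        ]
        tris, mat_idx, region = tris[keep], mat_idx[keep], region[keep]
        used = np.unique(tris)
        remap = -np.ones(len(nodes), dtype=np.int64)
        remap[used] = np.arange(len(used))
        nodes = nodes[used]
        tris = remap[tris]

    # --- node sets: electrodes (first listed wins at shared edges) ---
    r_n, z_n = nodes[:, 0], nodes[:, 1]
    node_sets: dict[str, np.ndarray] = {}
    electrode_potentials: dict[str, float] = {}
    claimed = np.zeros(len(nodes), dtype=bool)
    for k, patch in enumerate(scenario.electrodes):
        if patch.placement == "wound_bed":
            wound = scenario.wound
            w_n = geometry._cone_radius_clamped(z_n / MM, wound) * MM
            on_cone = (np.abs(r_n - w_n) < 10 * _TOL) & (z_n > -_TOL)
            mask = (
                on_cone
                & (r_n > patch.r_in_mm * MM - _TOL)
                & (r_n < patch.r_out_mm * MM + _TOL)
                & ~claimed
            )
            if patch.r_in_mm < 1e-12:
                # include the apex point
                apex = (np.abs(z_n - wound.depth_mm * MM) < _TOL) & (r_n < _TOL)
                mask |= apex & ~claimed
        else:
            if patch.placement == "interface" or (
                patch.placement == "sector" and patch.interface
            ):
                z_p = layers.interface_depth_mm(patch.interface) * MM
            else:
                z_p = 0.0
            mask = (
                (np.abs(z_n - z_p) < _TOL)
                & (r_n > patch.r_in_mm * MM - _TOL)
                & (r_n < patch.r_out_mm * MM + _TOL)
                & ~claimed
            )
        if not mask.any():
            raise MeshError(f"electrode patch {patch.name or k} matched no mesh nodes")
        claimed |= mask
        name = patch.name or f"electrode{k}"
        while name in node_sets:
            name = f"{name}_{k}"
        node_sets[name] = np.flatnonzero(mask)
        electrode_potentials[name] = patch.potential_mV * 1e-3

    # material-interface sets (diagnostic / export)
    names = [m.name for m in layers.materials]
    for i in range(1, layers.n_layers):
        z_p = layers.interfaces_mm[i] * MM
        node_sets[f"interface:{names[i - 1]}/{names[i]}"] = np.flatnonzero(
            np.abs(z_n - z_p) < _TOL
        )
    node_sets["surface"] = np.flatnonzero(np.abs(z_n) < _TOL)
    node_sets["axis"] = np.flatnonzero(np.abs(r_n) < _TOL)

    mesh = TriMesh(
        nodes=nodes,
        elements=np.ascontiguousarray(tris),
        element_material=mat_idx,
        materials=materials,
        element_region=region,
        node_sets=node_sets,
        electrode_potentials=electrode_potentials,
        scenario=scenario,
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Voxel grid


@dataclass(frozen=True)
class ElectrodeFaces:
    """Horizontal Dirichlet faces of one electrode patch on a voxel grid.

    ``k_level`` indexes the z grid plane; ``columns`` lists the (i, j) cell
    columns whose faces at that plane are clamped to ``potential_V``.
    """

    name: str
    potential_V: float
    k_level: int
    columns: np.ndarray


#: Default per-layer vertical spacing (mm) for the voxel grid.
DEFAULT_Z_SPACING_MM = {
    "stratum corneum": 0.007,
    "epidermis": 0.05,
    "dermis": 0.2,
    "subcutis": 0.3,
    "bath": 0.25,
}


@dataclass
class VoxelGrid:
    """Cartesian cell-centred grid with per-cell material tags.

    ``active`` marks cells that participate in the solve (inside the
    cylinder/bath and conductive); inactive faces carry zero flux.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    z_edges: np.ndarray
    cell_material: np.ndarray
    materials: list[Material]
    cell_region: np.ndarray
    active: np.ndarray
    electrode_faces: list[ElectrodeFaces]
    scenario: ScenarioConfig

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cell_material.shape

    @cached_property
    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            0.5 * (self.x_edges[1:] + self.x_edges[:-1]),
            0.5 * (self.y_edges[1:] + self.y_edges[:-1]),
            0.5 * (self.z_edges[1:] + self.z_edges[:-1]),
        )

    @cached_property
    def widths(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.diff(self.x_edges),
            np.diff(self.y_edges),
            np.diff(self.z_edges),
        )

    @cached_property
    def cell_volumes(self) -> np.ndarray:
        dx, dy, dz = self.widths
        return dx[:, None, None] * dy[None, :, None] * dz[None, None, :]

    @cached_property
    def cell_sigma(self) -> np.ndarray:
        sig = np.array([m.sigma for m in self.materials])
        return sig[self.cell_material]

    @cached_property
    def active_index(self) -> np.ndarray:
        """Flat unknown number per cell; -1 for inactive cells."""
        idx = -np.ones(self.shape, dtype=np.int64)
        idx[self.active] = np.arange(int(self.active.sum()))
        return idx

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def electrode_potentials(self) -> dict[str, float]:
        return {ef.name: ef.potential_V for ef in self.electrode_faces}


def _axis_edges(half_extent_mm: float, h_mm: float) -> np.ndarray:
    n = int(math.ceil(2 * half_extent_mm / h_mm))
    n += n % 2  # keep x = 0 a grid plane so +x/-x sampling is symmetric
    return np.linspace(-half_extent_mm, half_extent_mm, n + 1)


def generate_voxel_grid(
    scenario: ScenarioConfig,
    h_mm: float = 0.35,
    anisotropic_z: dict[str, float] | None = None,
    include_nonconductive: bool = False,
) -> VoxelGrid:
    """Cartesian grid for any scenario (required for sector electrodes).

    ``h_mm`` is the lateral voxel edge; ``anisotropic_z`` overrides the
    per-layer vertical spacing (mm, keyed by material name, plus ``"bath"``).
    Cell material is the region of the cell centre (staircase wound cone).
    """
    if h_mm <= 0:
        raise MeshError("voxel edge must be positive")
    z_spec = dict(DEFAULT_Z_SPACING_MM)
    if anisotropic_z:
        z_spec.update(anisotropic_z)

    layers = scenario.layers
    R_dom = scenario.cylinder_radius_mm + scenario.bath.margin_mm
    gen_bath = scenario.bath.height_mm > 0 and (
        include_nonconductive or not scenario.ambient.insulating
    )

    xy = _axis_edges(R_dom, h_mm)
    z_parts = []
    if gen_bath:
        dz = z_spec.get("bath", h_mm)
        n = max(2, int(round(scenario.bath.height_mm / dz)))
        z_parts.append(np.linspace(-scenario.bath.height_mm, 0.0, n + 1)[:-1])
    z0 = 0.0
    for mat, t in layers.layers:
        dz = z_spec.get(mat.name, h_mm)
        n = max(2 if t < 0.05 else 1, int(round(t / dz)))
        z_parts.append(np.linspace(z0, z0 + t, n + 1)[:-1])
        z0 += t
    z_parts.append(np.array([z0]))
    z_edges = np.concatenate(z_parts)

    xc = 0.5 * (xy[1:] + xy[:-1])
    zc = 0.5 * (z_edges[1:] + z_edges[:-1])
    X, Y, Z = np.meshgrid(xc, xc, zc, indexing="ij")
    Rc = np.hypot(X, Y)
    region = geometry.classify_points(Rc.ravel(), Z.ravel(), scenario).reshape(Rc.shape)

    materials = list(layers.materials) + [scenario.ambient]
    ambient_idx = len(materials) - 1
    mat_idx = np.full(region.shape, ambient_idx, dtype=np.int64)
    for i in range(layers.n_layers):
        mat_idx[region == int(SKIN_LAYER_LABELS[i])] = i

    active = region != int(RegionLabel.outside)
    if not include_nonconductive:
        insulating = np.array([m.insulating for m in materials])
        active &= ~insulating[mat_idx]

    # --- electrode face sets ---
    kz0 = int(np.argmin(np.abs(z_edges)))
    theta = np.degrees(np.arctan2(Y[:, :, 0], X[:, :, 0]))
    electrode_faces: list[ElectrodeFaces] = []
    claimed_by_plane: dict[int, np.ndarray] = {}
    for k, patch in enumerate(scenario.electrodes):
        if patch.placement == "wound_bed":
            raise MeshError(
                "wound-bed electrodes are supported on the axisymmetric mesh only"
            )
        if patch.placement == "interface" or (
            patch.placement == "sector" and patch.interface
        ):
            z_p = layers.interface_depth_mm(patch.interface)
            k_level = int(np.argmin(np.abs(z_edges - z_p)))
            if abs(z_edges[k_level] - z_p) > 1e-9:
                raise MeshError(
                    f"interface patch plane z = {z_p} mm is not a grid plane"
                )
        else:
            k_level = kz0
        rc = Rc[:, :, 0]
        mask = (rc >= patch.r_in_mm) & (rc <= patch.r_out_mm)
        if patch.placement == "sector":
            lo, hi = patch.theta_min_deg, patch.theta_max_deg
            th = (theta - lo) % 360.0
            mask &= th <= (hi - lo)
        claimed = claimed_by_plane.setdefault(
            k_level, np.zeros(theta.shape, dtype=bool)
        )
        mask &= ~claimed
        if not mask.any():
            raise MeshError(f"electrode patch {patch.name or k} matched no voxels")
        claimed |= mask
        name = patch.name or f"electrode{k}"
        electrode_faces.append(
            ElectrodeFaces(
                name=name,
                potential_V=patch.potential_mV * 1e-3,
                k_level=k_level,
                columns=np.argwhere(mask),
            )
        )

    return VoxelGrid(
        x_edges=xy * MM,
        y_edges=xy * MM,
        z_edges=z_edges * MM,
        cell_material=mat_idx,
        materials=materials,
        cell_region=region,
        active=active,
        electrode_faces=electrode_faces,
        scenario=scenario,
    )
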