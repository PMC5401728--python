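"""Analytic geometry of the wound model.

The domain is a cylinder of skin (four plane-parallel layers, listed from
the outside in) with a conical wound cut into it, optionally capped by a
bath of ambient medium above the skin surface.

Coordinate convention: cylindrical ``(r, theta, z)`` with the origin at the
centre of the wound mouth on the skin surface and *z increasing downward*
into the tissue.  The bath occupies negative ``z``.  All public interfaces
take millimetres; conversion to SI happens where meshes are built.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WoundSpec",
    "BathSpec",
    "RegionLabel",
    "SKIN_LAYER_LABELS",
    "wound_radius_at_depth",
    "classify_point",
    "classify_points",
    "layer_volume",
    "wound_cavity_volume",
]


class RegionLabel(enum.IntEnum):
    """Disjoint regions of the model; every point maps to exactly one."""

    bath = 0
    wound_cavity = 1
    stratum_corneum = 2
    epidermis = 3
    dermis = 4
    subcutis = 5
    outside = 6


#: Labels of the skin layers, outermost first.
SKIN_LAYER_LABELS = (
    RegionLabel.stratum_corneum,
    RegionLabel.epidermis,
    RegionLabel.dermis,
    RegionLabel.subcutis,
)


@dataclass(frozen=True)
class WoundSpec:
    """Conical wound: a circular mouth of ``top_radius_mm`` at the skin
    surface, tapering linearly to an apex ``depth_mm`` below it."""

    top_radius_mm: float = 2.0
    depth_mm: float = 5.514

    def __post_init__(self) -> None:
        if not self.top_radius_mm > 0:
            raise ValueError("wound top radius must be positive")
        if not self.depth_mm > 0:
            raise ValueError("wound depth must be positive")


@dataclass(frozen=True)
class BathSpec:
    """Extent of the ambient-medium bath: a slab of ``height_mm`` above the
    skin surface and an optional lateral sleeve of ``margin_mm`` around the
    skin cylinder."""

    height_mm: float = 2.0
    margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.height_mm < 0 or self.margin_mm < 0:
            raise ValueError("bath dimensions must be non-negative")


def wound_radius_at_depth(z_mm: float, wound: WoundSpec) -> float:
    """Radius of the wound cone at depth ``z_mm`` below the skin surface.

    Linear profile: ``top_radius * (1 - z/depth)``.
    """
    if z_mm < 0 or z_mm > wound.depth_mm:
        raise ValueError(
            f"depth {z_mm} mm outside the wound extent [0, {wound.depth_mm}] mm"
        )
    return wound.top_radius_mm * (1.0 - z_mm / wound.depth_mm)


def _cone_radius_clamped(z_mm: np.ndarray, wound: WoundSpec | None) -> np.ndarray:
    """Cone radius at depth z, zero outside [0, depth]; vectorised."""
    if wound is None:
        return np.zeros_like(np.asarray(z_mm, dtype=float))
    z = np.asarray(z_mm, dtype=float)
    w = wound.top_radius_mm * (1.0 - z / wound.depth_mm)
    return np.where((z >= 0) & (z <= wound.depth_mm), np.maximum(w, 0.0), 0.0)


def classify_points(r_mm, z_mm, scenario) -> np.ndarray:
    """Vectorised region classification; returns ``RegionLabel`` codes.

    ``scenario`` needs attributes ``layers`` (with ``.interfaces_mm`` /
    ``.total_thickness_mm`` / ``.n_layers``), ``wound``, ``cylinder_radius_mm``
    and ``bath``.
    """
    r = np.asarray(r_mm, dtype=float)
    z = np.asarray(z_mm, dtype=float)
    r, z = np.broadcast_arrays(r, z)
    out = np.full(r.shape, int(RegionLabel.outside), dtype=np.int64)

    R = scenario.cylinder_radius_mm
    total = scenario.layers.total_thickness_mm
    bath = scenario.bath
    h, margin = bath.height_mm, bath.margin_mm

    # bath: slab above the surface plus optional lateral sleeve
    in_cap = (z < 0) & (z >= -h) & (r <= R + margin)
    in_sleeve = (margin > 0) & (z >= 0) & (z <= total) & (r > R) & (r <= R + margin)
    out[in_cap | in_sleeve] = int(RegionLabel.bath)

    in_skin_cyl = (z >= 0) & (z <= total) & (r <= R)
    w = _cone_radius_clamped(z, scenario.wound)
    in_cavity = in_skin_cyl & (r < w)
    in_tissue = in_skin_cyl & ~in_cavity

    # assign skin layers by depth interval
    interfaces = scenario.layers.interfaces_mm  # length n_layers + 1, starts at 0
    if scenario.layers.n_layers > len(SKIN_LAYER_LABELS):
        raise ValueError("more layers than nameable skin regions")
    for i in range(scenario.layers.n_layers):
        lo, hi = interfaces[i], interfaces[i + 1]
        sel = in_tissue & (z >= lo) & (z <= hi if i == scenario.layers.n_layers - 1 else z < hi)
        out[sel] = int(SKIN_LAYER_LABELS[i])
    out[in_cavity] = int(RegionLabel.wound_cavity)
    return out


def classify_point(r_mm: float, z_mm: float, scenario) -> RegionLabel:
    """Classify a single point ``(r, z)`` (mm, z down from the surface)."""
    return RegionLabel(int(classify_points(r_mm, z_mm, scenario)[()]))


def _frustum_volume_mm3(r0: float, r1: float, h: float) -> float:
    """Volume of a conical frustum of end radii r0, r1 and height h."""
    return math.pi * h * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0


def wound_cavity_volume(scenario) -> float:
    """Exact volume (mm^3) of the wound cavity inside the skin cylinder."""
    w = scenario.wound
    if w is None:
        return 0.0
    depth = min(w.depth_mm, scenario.layers.total_thickness_mm)
    r_bottom = w.top_radius_mm * (1.0 - depth / w.depth_mm)
    return _frustum_volume_mm3(w.top_radius_mm, r_bottom, depth)


def layer_volume(label: RegionLabel, scenario) -> float:
    """Exact analytic volume (mm^3) of one skin layer: the cylindrical slab
    minus the part of the wound cone crossing it."""
    if label not in SKIN_LAYER_LABELS:
        raise ValueError(f"{label!r} is not a skin layer")
    i = SKIN_LAYER_LABELS.index(label)
    if i >= scenario.layers.n_layers:
        raise ValueError(f"scenario has no layer {label.name}")
    interfaces = scenario.layers.interfaces_mm
    z0, z1 = interfaces[i], interfaces[i + 1]
    slab = math.pi * scenario.cylinder_radius_mm**2 * (z1 - z0)
    w = scenario.wound
    if w is None:
        return slab
    a, b = max(z0, 0.0), min(z1, w.depth_mm)
    if b <= a:
        return slab
    r0 = wound_radius_at_depth(a, w)
    r1 = wound_radius_at_depth(b, w)
    return slab - _frustum_volume_mm3(r0, r1, b - a)
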