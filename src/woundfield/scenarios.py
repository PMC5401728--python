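"""Stimulation scenarios: materials, layer stack and electrode layouts.

This module is the package's fixture generator.  It encodes the tissue
parameters of the four-layer skin model and the stimulation scenarios
studied with it:

* ``endogenous`` — the transepithelial potential (TEP) battery: intact skin
  surface grounded, +30 mV on the epidermis–dermis interface where it is
  not interrupted by the wound.
* ``geo1`` … ``geo4`` — concentric surface-electrode layouts (a grounded
  disc over the wound, a positive annulus on the intact skin, with varying
  disc radii and ring gaps).  These are axisymmetric.
* ``geo5`` — two opposed angular-sector electrodes on the intact skin with
  nothing over the wound (breaks axisymmetry); ``geo5_air`` is the same
  layout with the ambient medium switched from buffer to air.

External interfaces use the model's natural units (mm, mV); meshing and
solving convert to SI at the discretization boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from .geometry import BathSpec, WoundSpec, wound_radius_at_depth

__all__ = [
    "Material",
    "LayerStack",
    "ElectrodePatch",
    "ScenarioConfig",
    "ScenarioError",
    "SCENARIO_NAMES",
    "default_materials",
    "default_layer_stack",
    "build_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]

#: Conductivity below which a medium is treated as effectively insulating
#: (elements of such media are excised from the solve by default).
SIGMA_INSULATOR = 1e-9


class ScenarioError(ValueError):
    """Invalid or inconsistent scenario description."""


@dataclass(frozen=True)
class Material:
    """Homogeneous isotropic conductor.

    ``sigma`` is the DC conductivity in S/m.  ``eps_r`` (relative
    permittivity) is carried as metadata only: under steady DC the problem
    is purely resistive and permittivity plays no role in the solve.
    """

    name: str
    sigma: float
    eps_r: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ScenarioError(f"material {self.name!r}: sigma must be > 0")
        if self.eps_r <= 0:
            raise ScenarioError(f"material {self.name!r}: eps_r must be > 0")

    @property
    def insulating(self) -> bool:
        return self.sigma < SIGMA_INSULATOR


@dataclass(frozen=True)
class LayerStack:
    """Ordered plane-parallel layers, outermost (top) first."""

    layers: tuple[tuple[Material, float], ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ScenarioError("layer stack must contain at least one layer")
        for mat, t in self.layers:
            if t <= 0:
                raise ScenarioError(f"layer {mat.name!r}: thickness must be > 0")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def thicknesses_mm(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.layers)

    @property
    def materials(self) -> tuple[Material, ...]:
        return tuple(m for m, _ in self.layers)

    @property
    def total_thickness_mm(self) -> float:
        return sum(self.thicknesses_mm)

    @property
    def interfaces_mm(self) -> tuple[float, ...]:
        """Depths of the layer boundaries, starting at the surface (0)."""
        z, out = 0.0, [0.0]
        for t in self.thicknesses_mm:
            z += t
            out.append(z)
        return tuple(out)

    def interface_depth_mm(self, name: str) -> float:
        """Depth of a named boundary: ``"top"``, ``"bottom"`` or
        ``"<upper layer>/<lower layer>"`` (e.g. ``"epidermis/dermis"``)."""
        if name == "top":
            return 0.0
        if name == "bottom":
            return self.total_thickness_mm
        try:
            upper, lower = name.split("/")
        except ValueError:
            raise ScenarioError(f"malformed interface name {name!r}") from None
        names = [m.name for m in self.materials]
        for i in range(self.n_layers - 1):
            if names[i] == upper and names[i + 1] == lower:
                return self.interfaces_mm[i + 1]
        raise ScenarioError(f"no interface {name!r} in stack {names}")


@dataclass(frozen=True)
class ElectrodePatch:
    """Ideal (equipotential Dirichlet) electrode patch.

    Placements:

    * ``"top"`` — annulus ``r_in <= r <= r_out`` on the skin surface
      (``r_in = 0`` gives a disc); covers the wound mouth where it overlaps.
    * ``"sector"`` — angular sector of an annulus spanning
      ``theta_min_deg .. theta_max_deg``, on the skin surface or (with an
      ``interface`` name) on an internal plane.
    * ``"interface"`` — annulus on the named internal layer boundary
      (``interface`` attribute), e.g. the epidermis–dermis interface that
      carries the TEP in the endogenous scenario, or the corneum–epidermis
      plane where a stimulation electrode couples to viable tissue through
      the microscopically thin stratum corneum.  ``"bottom"`` addresses the
      base of the skin cylinder.
    * ``"wound_bed"`` — conforming electrode on the conical wound surface,
      between projected radii ``r_in`` and ``r_out`` (a dressing pressed
      into the wound).
    """

    placement: str
    r_in_mm: float
    r_out_mm: float
    potential_mV: float
    theta_min_deg: float = 0.0
    theta_max_deg: float = 360.0
    interface: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.placement not in ("top", "sector", "interface", "wound_bed"):
            raise ScenarioError(f"unknown placement {self.placement!r}")
        if not self.r_in_mm < self.r_out_mm:
            raise ScenarioError("electrode patch requires r_in < r_out")
        if self.r_in_mm < 0:
            raise ScenarioError("electrode patch requires r_in >= 0")
        if self.placement == "sector" and not self.theta_min_deg < self.theta_max_deg:
            raise ScenarioError("sector patch requires theta_min < theta_max")
        if self.placement == "interface" and not self.interface:
            raise ScenarioError("interface patch requires an interface name")

    @property
    def axisymmetric(self) -> bool:
        return self.placement != "sector"

    def theta_range_rad(self) -> tuple[float, float]:
        return math.radians(self.theta_min_deg), math.radians(self.theta_max_deg)


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float], tol: float) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) > tol


def _sectors_overlap(a: ElectrodePatch, b: ElectrodePatch, tol: float) -> bool:
    if not _intervals_overlap((a.r_in_mm, a.r_out_mm), (b.r_in_mm, b.r_out_mm), tol):
        return False
    # compare angular intervals modulo 360
    for shift in (-360.0, 0.0, 360.0):
        if _intervals_overlap(
            (a.theta_min_deg + shift, a.theta_max_deg + shift),
            (b.theta_min_deg, b.theta_max_deg),
            1e-9,
        ):
            return True
    return False


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete, solvable stimulation problem."""

    name: str
    layers: LayerStack
    wound: WoundSpec | None
    cylinder_radius_mm: float
    bath: BathSpec
    ambient: Material
    electrodes: tuple[ElectrodePatch, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        if self.cylinder_radius_mm <= 0:
            raise ScenarioError("cylinder radius must be positive")
        if self.wound is not None:
            if not self.wound.top_radius_mm < self.cylinder_radius_mm:
                raise ScenarioError("wound mouth must fit inside the skin cylinder")
            if self.wound.depth_mm > self.layers.total_thickness_mm + tol:
                raise ScenarioError("wound deeper than the skin")
        if len(self.electrodes) < 2:
            raise ScenarioError("need at least a source and a ground electrode")
        potentials = {p.potential_mV for p in self.electrodes}
        if len(potentials) < 2:
            raise ScenarioError("electrodes must carry at least two distinct potentials")
        for p in self.electrodes:
            if p.r_out_mm > self.cylinder_radius_mm + tol:
                raise ScenarioError(
                    f"patch {p.name or p.placement!r} extends beyond the skin cylinder"
                )
            if p.placement == "interface" or (p.placement == "sector" and p.interface):
                self.layers.interface_depth_mm(p.interface)  # raises if unknown
            if p.placement == "wound_bed":
                if self.wound is None:
                    raise ScenarioError("wound-bed electrode requires a wound")
                if p.r_out_mm > self.wound.top_radius_mm + tol:
                    raise ScenarioError(
                        "wound-bed electrode extends beyond the wound mouth"
                    )
        # patches at different potentials must not overlap with positive
        # measure on the same surface
        def surface_of(p: ElectrodePatch):
            if p.placement == "wound_bed":
                return ("wound_bed",)
            if p.placement == "interface" or (p.placement == "sector" and p.interface):
                return ("interface", p.interface)
            return ("top",)

        for i, a in enumerate(self.electrodes):
            for b in self.electrodes[i + 1 :]:
                if a.potential_mV == b.potential_mV:
                    continue
                if surface_of(a) != surface_of(b):
                    continue
                if a.placement == "sector" or b.placement == "sector":
                    aa = a if a.placement == "sector" else replace(
                        a, placement="sector", theta_min_deg=0.0, theta_max_deg=360.0
                    )
                    bb = b if b.placement == "sector" else replace(
                        b, placement="sector", theta_min_deg=0.0, theta_max_deg=360.0
                    )
                    clash = _sectors_overlap(aa, bb, tol)
                else:
                    clash = _intervals_overlap(
                        (a.r_in_mm, a.r_out_mm), (b.r_in_mm, b.r_out_mm), tol
                    )
                if clash:
                    raise ScenarioError(
                        f"patches {a.name or a.placement!r} and "
                        f"{b.name or b.placement!r} overlap at distinct potentials"
                    )

    @property
    def axisymmetric(self) -> bool:
        return all(p.axisymmetric for p in self.electrodes)

    @property
    def potentials_mV(self) -> tuple[float, ...]:
        return tuple(sorted({p.potential_mV for p in self.electrodes}))

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


# --- Table of tissue/medium parameters -------------------------------------

_MATERIAL_TABLE = (
    # name, sigma (S/m), eps_r
    ("PBS", 1.4, 80.0),
    ("stratum corneum", 2e-6, 5e2),
    ("epidermis", 0.026, 1e6),
    ("dermis", 0.222, 1e8),
    ("subcutis", 0.08, 1e7),
    # Air: nominal insulator.  The tiny conductivity is a numerical
    # placeholder; the solvers excise insulating elements by default.
    ("air", 1e-12, 1.0),
)

_LAYER_THICKNESS_MM = {
    "stratum corneum": 0.014,
    "epidermis": 0.3,
    "dermis": 2.2,
    "subcutis": 3.0,
}

SCENARIO_NAMES = (
    "endogenous",
    "geo1",
    "geo2",
    "geo3",
    "geo4",
    "geo5",
    "geo5_air",
)

#: Applied stimulation / transepithelial potential in mV.
DEFAULT_POTENTIAL_MV = 30.0
#: Skin cylinder radius in mm.
DEFAULT_RADIUS_MM = 10.0


def default_materials() -> dict[str, Material]:
    """The model's media: buffer, the four skin layers and air."""
    return {n: Material(n, s, e) for n, s, e in _MATERIAL_TABLE}


def default_layer_stack(materials: dict[str, Material] | None = None) -> LayerStack:
    """The four-layer skin stack (total thickness 5.514 mm)."""
    mats = materials or default_materials()
    return LayerStack(
        tuple((mats[n], t) for n, t in _LAYER_THICKNESS_MM.items())
    )


#: Internal plane where a surface electrode couples to viable tissue.  The
#: stratum corneum is a 14 µm sheet six orders of magnitude more resistive
#: than the layers below: an electrode modelled as an equipotential on top
#: of an intact corneum would be screened almost completely, while wound
#: dressings and stimulation electrodes in practice couple through the
#: hydrated/compromised corneum.  Stimulation patches on "intact skin" are
#: therefore clamped at the corneum-epidermis plane.
CONTACT_INTERFACE = "stratum corneum/epidermis"


def _concentric_electrodes(
    neg_placement: str,
    neg_r_out: float,
    pos_r_in: float,
    pos_r_out: float,
    v_mV: float,
    neg_r_in: float = 0.0,
) -> tuple[ElectrodePatch, ...]:
    """Concentric layout: grounded cathode over/in the wound, positive
    annulus on the intact skin.

    A cathode that covers the whole wound bed conforms to the cone
    (``wound_bed``); a smaller disc "placed on the wound" spans the mouth
    plane (``top``).  The anode couples at the subcorneal plane (see
    :data:`CONTACT_INTERFACE`).  The ground is listed first: where patches
    touch, shared mesh nodes go to it.
    """
    return (
        ElectrodePatch(neg_placement, neg_r_in, neg_r_out, 0.0, name="negative"),
        ElectrodePatch(
            "interface", pos_r_in, pos_r_out, v_mV, interface=CONTACT_INTERFACE,
            name="positive",
        ),
    )


def build_scenario(name: str, overrides: dict | None = None) -> ScenarioConfig:
    """Build one of the named scenarios, optionally overriding parameters.

    Generic override keys: ``potential_mV``, ``cylinder_radius_mm``,
    ``wound_radius_mm``, ``wound_depth_mm``, ``bath_height_mm``,
    ``bath_margin_mm``, ``ambient`` (material name).  Concentric layouts
    (geo1–geo4) additionally accept ``neg_r_in``, ``neg_r_out``,
    ``pos_r_in``, ``pos_r_out`` (mm); the sector layout (geo5) accepts
    ``sector_r_in``, ``sector_r_out``, ``sector_half_angle_deg``.
    """
    if name not in SCENARIO_NAMES:
        raise ScenarioError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    ov = dict(overrides or {})
    mats = default_materials()

    v = float(ov.pop("potential_mV", DEFAULT_POTENTIAL_MV))
    R = float(ov.pop("cylinder_radius_mm", DEFAULT_RADIUS_MM))
    wound = WoundSpec(
        top_radius_mm=float(ov.pop("wound_radius_mm", 2.0)),
        depth_mm=float(ov.pop("wound_depth_mm", 5.514)),
    )
    bath = BathSpec(
        height_mm=float(ov.pop("bath_height_mm", 2.0)),
        margin_mm=float(ov.pop("bath_margin_mm", 0.0)),
    )
    ambient_name = ov.pop("ambient", "air" if name == "geo5_air" else "PBS")
    if ambient_name not in mats:
        raise ScenarioError(f"unknown ambient material {ambient_name!r}")
    ambient = mats[ambient_name]
    layers = default_layer_stack(mats)

    # default cathode placement and radii (mm): negative electrode outer
    # radius, positive annulus inner radius.  geo1/geo3 cathode diameter
    # 4 mm covering the whole wound bed; geo2/geo4 a 3 mm disc at the wound
    # mouth; ring gaps 0 / 0.5 / 2 / 2.5 mm; positive electrode covers the
    # remaining intact skin out to the cylinder edge.
    concentric_defaults = {
        "geo1": ("wound_bed", 2.0, 2.0),
        "geo2": ("top", 1.5, 2.0),
        "geo3": ("wound_bed", 2.0, 4.0),
        "geo4": ("top", 1.5, 4.0),
    }

    if name == "endogenous":
        # TEP battery: ground on the uninjured surface, +v on the
        # epidermis-dermis interface outside the wound cone.
        z_if = layers.interface_depth_mm("epidermis/dermis")
        r_cone = (
            wound_radius_at_depth(z_if, wound) if z_if <= wound.depth_mm else 0.0
        )
        electrodes = (
            ElectrodePatch("top", wound.top_radius_mm, R, 0.0, name="surface ground"),
            ElectrodePatch(
                "interface",
                r_cone,
                R,
                v,
                interface="epidermis/dermis",
                name="TEP source",
            ),
        )
    elif name in concentric_defaults:
        neg_placement, neg_r_out, pos_r_in = concentric_defaults[name]
        neg_placement = str(ov.pop("neg_placement", neg_placement))
        neg_r_in = float(ov.pop("neg_r_in", 0.0))
        neg_r_out = float(ov.pop("neg_r_out", neg_r_out))
        pos_r_in = float(ov.pop("pos_r_in", pos_r_in))
        pos_r_out = float(ov.pop("pos_r_out", R))
        electrodes = _concentric_electrodes(
            neg_placement, neg_r_out, pos_r_in, pos_r_out, v, neg_r_in
        )
    else:  # geo5 / geo5_air
        # each electrode covers one side of the intact skin: wide sectors
        # with a 0.5 mm standoff from the wound rim (no electrode over the
        # wound) and 20 deg separations between the two pads
        r_in = float(ov.pop("sector_r_in", 2.5))
        r_out = float(ov.pop("sector_r_out", R))
        half = float(ov.pop("sector_half_angle_deg", 80.0))
        electrodes = (
            ElectrodePatch(
                "sector", r_in, r_out, 0.0, 180.0 - half, 180.0 + half,
                interface=CONTACT_INTERFACE, name="negative",
            ),
            ElectrodePatch(
                "sector", r_in, r_out, v, -half, half,
                interface=CONTACT_INTERFACE, name="positive",
            ),
        )

    if ov:
        raise ScenarioError(f"unknown override(s) for {name!r}: {sorted(ov)}")
    return ScenarioConfig(
        name=name,
        layers=layers,
        wound=wound,
        cylinder_radius_mm=R,
        bath=bath,
        ambient=ambient,
        electrodes=electrodes,
    )


# --- Serialization ----------------------------------------------------------


def _material_to_dict(m: Material) -> dict:
    return {"name": m.name, "sigma": m.sigma, "eps_r": m.eps_r}


def scenario_to_dict(sc: ScenarioConfig) -> dict:
    return {
        "name": sc.name,
        "layers": [
            {"material": _material_to_dict(m), "thickness_mm": t}
            for m, t in sc.layers.layers
        ],
        "wound": (
            None
            if sc.wound is None
            else {"top_radius_mm": sc.wound.top_radius_mm, "depth_mm": sc.wound.depth_mm}
        ),
        "cylinder_radius_mm": sc.cylinder_radius_mm,
        "bath": {"height_mm": sc.bath.height_mm, "margin_mm": sc.bath.margin_mm},
        "ambient": _material_to_dict(sc.ambient),
        "electrodes": [
            {
                "placement": p.placement,
                "r_in_mm": p.r_in_mm,
                "r_out_mm": p.r_out_mm,
                "potential_mV": p.potential_mV,
                "theta_min_deg": p.theta_min_deg,
                "theta_max_deg": p.theta_max_deg,
                "interface": p.interface,
                "name": p.name,
            }
            for p in sc.electrodes
        ],
    }


def scenario_from_dict(d: dict) -> ScenarioConfig:
    return ScenarioConfig(
        name=d["name"],
        layers=LayerStack(
            tuple(
                (Material(**row["material"]), float(row["thickness_mm"]))
                for row in d["layers"]
            )
        ),
        wound=None if d["wound"] is None else WoundSpec(**d["wound"]),
        cylinder_radius_mm=float(d["cylinder_radius_mm"]),
        bath=BathSpec(**d["bath"]),
        ambient=Material(**d["ambient"]),
        electrodes=tuple(ElectrodePatch(**row) for row in d["electrodes"]),
    )


def save_scenario(sc: ScenarioConfig, path) -> None:
    """Write a scenario to a human-editable YAML file (lossless)."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
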