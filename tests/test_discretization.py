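"""Meshing: interface conformity, material tags, measures, electrode sets."""

import math

import numpy as np
import pytest

from woundfield.discretization import (
    MeshError,
    generate_axisymmetric_mesh,
    generate_voxel_grid,
)
from woundfield.geometry import (
    RegionLabel,
    SKIN_LAYER_LABELS,
    classify_points,
    layer_volume,
    wound_cavity_volume,
)
from woundfield.scenarios import build_scenario

MM = 1e-3


@pytest.fixture(scope="module")
def geo1_mesh():
    return generate_axisymmetric_mesh(build_scenario("geo1"), resolution_mm=0.3)


class TestAxisymmetricMesh:
    def test_positive_areas_and_radii(self, geo1_mesh):
        geo1_mesh.validate()
        assert (geo1_mesh.element_areas > 0).all()
        assert (geo1_mesh.nodes[:, 0] >= -1e-12).all()

    def test_material_matches_centroid_classification(self, geo1_mesh, rng):
        """Assigned material equals geometric classification at centroids."""
        idx = rng.choice(geo1_mesh.n_elements, size=1000, replace=False)
        cent = geo1_mesh.element_centroids[idx] / MM
        labels = classify_points(cent[:, 0], cent[:, 1], geo1_mesh.scenario)
        assert (labels == geo1_mesh.element_region[idx]).all()

    def test_per_material_volume_is_exact(self, geo1_mesh):
        """The conforming mesh integrates each layer's solid of revolution
        exactly (straight interfaces, centroid-radius quadrature)."""
        sc = geo1_mesh.scenario
        for i, label in enumerate(SKIN_LAYER_LABELS):
            sel = geo1_mesh.element_region == int(label)
            vol = geo1_mesh.element_measures[sel].sum() / MM**3
            assert vol == pytest.approx(layer_volume(label, sc), rel=1e-9)
        cav = geo1_mesh.element_region == int(RegionLabel.wound_cavity)
        assert geo1_mesh.element_measures[cav].sum() / MM**3 == pytest.approx(
            wound_cavity_volume(sc), rel=1e-9
        )

    def test_thin_corneum_has_at_least_two_rows(self, geo1_mesh):
        z = geo1_mesh.element_centroids[:, 1] / MM
        sel = geo1_mesh.element_region == int(RegionLabel.stratum_corneum)
        assert len(np.unique(np.round(z[sel], 6))) >= 2

    def test_refinement_preserves_material_volumes(self):
        sc = build_scenario("geo2")
        vols = []
        for res in (0.4, 0.2):
            mesh = generate_axisymmetric_mesh(sc, resolution_mm=res)
            vols.append(
                [
                    mesh.element_measures[mesh.element_region == int(l)].sum()
                    for l in SKIN_LAYER_LABELS
                ]
            )
        for a, b in zip(*vols):
            assert abs(a - b) / b < 0.01

    def test_electrode_sets_disjoint_and_on_their_surfaces(self, geo1_mesh):
        names = list(geo1_mesh.electrode_potentials)
        sets = [set(geo1_mesh.node_sets[n].tolist()) for n in names]
        assert not (sets[0] & sets[1])
        # geo1 cathode conforms to the wound cone
        neg = geo1_mesh.node_sets[names[0]]
        r, z = geo1_mesh.nodes[neg, 0] / MM, geo1_mesh.nodes[neg, 1] / MM
        w = 2.0 * (1 - z / 5.514)
        assert np.allclose(r, w, atol=1e-6)

    def test_sector_scenario_refused(self):
        with pytest.raises(MeshError, match="voxel"):
            generate_axisymmetric_mesh(build_scenario("geo5"))

    def test_too_coarse_resolution_refused(self):
        with pytest.raises(MeshError, match="coarse"):
            generate_axisymmetric_mesh(build_scenario("geo1"), resolution_mm=5.0)


class TestVoxelGrid:
    def test_invalid_edge_refused(self):
        with pytest.raises(MeshError):
            generate_voxel_grid(build_scenario("geo5"), h_mm=0.0)

    def test_cavity_fraction_matches_cone_volume(self):
        sc = build_scenario("geo5")
        grid = generate_voxel_grid(sc, h_mm=0.4)
        cav = grid.cell_region == int(RegionLabel.wound_cavity)
        vol = grid.cell_volumes[cav].sum() / MM**3
        assert vol == pytest.approx(wound_cavity_volume(sc), rel=0.08)

    def test_geo5_has_two_opposed_electrode_sets(self):
        grid = generate_voxel_grid(build_scenario("geo5"), h_mm=0.5)
        assert len(grid.electrode_faces) == 2
        xs = {}
        xc = 0.5 * (grid.x_edges[1:] + grid.x_edges[:-1])
        for ef in grid.electrode_faces:
            cols = {(int(i), int(j)) for i, j in ef.columns}
            xs[ef.name] = np.mean([xc[i] for i, _ in cols])
            assert cols  # non-empty
        sets = [
            {(int(i), int(j)) for i, j in ef.columns} for ef in grid.electrode_faces
        ]
        assert not (sets[0] & sets[1])
        # opposite sides of the wound along x
        a, b = xs.values()
        assert a * b < 0

    def test_interfaces_are_grid_planes(self):
        grid = generate_voxel_grid(build_scenario("geo5"), h_mm=0.5)
        z = grid.z_edges / MM
        for depth in (0.0, 0.014, 0.314, 2.514, 5.514):
            assert np.min(np.abs(z - depth)) < 1e-9

    def test_air_ambient_excises_bath_and_cavity(self):
        grid = generate_voxel_grid(build_scenario("geo5_air"), h_mm=0.5)
        assert (grid.z_edges >= -1e-12).all()  # no bath layer generated
        cav = grid.cell_region == int(RegionLabel.wound_cavity)
        assert not grid.active[cav].any()
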