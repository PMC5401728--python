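"""Scenario fixtures: tissue parameters, electrode layouts, serialization."""

import pytest

from woundfield.geometry import BathSpec
from woundfield.scenarios import (
    SCENARIO_NAMES,
    ElectrodePatch,
    ScenarioConfig,
    ScenarioError,
    build_scenario,
    default_layer_stack,
    default_materials,
    load_scenario,
    save_scenario,
    scenario_from_dict,
    scenario_to_dict,
)


class TestMaterials:
    def test_table_values(self):
        mats = default_materials()
        assert mats["stratum corneum"].sigma == pytest.approx(2e-6)
        assert mats["PBS"].sigma == pytest.approx(1.4)
        assert mats["PBS"].eps_r == pytest.approx(80)
        assert mats["epidermis"].sigma == pytest.approx(0.026)
        assert mats["dermis"].sigma == pytest.approx(0.222)
        assert mats["subcutis"].sigma == pytest.approx(0.08)
        assert set(mats) == {
            "PBS", "stratum corneum", "epidermis", "dermis", "subcutis", "air",
        }

    def test_total_skin_thickness(self):
        assert default_layer_stack().total_thickness_mm == pytest.approx(5.514)

    def test_invalid_material_rejected(self):
        from woundfield.scenarios import Material

        with pytest.raises(ScenarioError):
            Material("bad", -1.0, 1.0)


class TestBuildScenario:
    def test_geo1_cathode_covers_the_4mm_wound(self):
        neg = build_scenario("geo1").electrodes[0]
        assert neg.potential_mV == 0
        assert (neg.r_in_mm, neg.r_out_mm) == (0.0, 2.0)  # diameter 4 mm

    def test_geo3_ring_gap_is_2mm(self):
        sc = build_scenario("geo3")
        neg, pos = sc.electrodes
        assert pos.r_in_mm - neg.r_out_mm == pytest.approx(2.0)

    def test_geo2_gap_is_half_mm_at_the_mouth(self):
        sc = build_scenario("geo2")
        neg, pos = sc.electrodes
        assert neg.r_out_mm == pytest.approx(1.5)  # diameter 3 mm
        assert pos.r_in_mm == pytest.approx(2.0)

    def test_endogenous_tep_on_epidermis_dermis_interface(self):
        sc = build_scenario("endogenous")
        src = [p for p in sc.electrodes if p.potential_mV == 30.0]
        assert len(src) == 1
        assert src[0].placement == "interface"
        assert src[0].interface == "epidermis/dermis"

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ScenarioError, match="geo1"):
            build_scenario("geo9")

    def test_unknown_override_rejected(self):
        with pytest.raises(ScenarioError, match="unknown override"):
            build_scenario("geo1", {"frobnicate": 1})

    def test_every_scenario_validates(self):
        for name in SCENARIO_NAMES:
            sc = build_scenario(name)
            sc.validate()
            assert set(sc.potentials_mV) == {0.0, 30.0}

    def test_axisymmetry_split(self):
        for name in ("endogenous", "geo1", "geo2", "geo3", "geo4"):
            assert build_scenario(name).axisymmetric
        for name in ("geo5", "geo5_air"):
            assert not build_scenario(name).axisymmetric

    def test_geo5_air_ambient(self):
        assert build_scenario("geo5_air").ambient.name == "air"
        assert build_scenario("geo5").ambient.name == "PBS"


class TestValidation:
    def test_overlapping_patches_rejected(self):
        sc = build_scenario("geo1")
        bad = (
            ElectrodePatch("top", 0.0, 3.0, 0.0, name="a"),
            ElectrodePatch("top", 2.0, 10.0, 30.0, name="b"),
        )
        with pytest.raises(ScenarioError, match="overlap"):
            ScenarioConfig(
                name="bad",
                layers=sc.layers,
                wound=sc.wound,
                cylinder_radius_mm=10.0,
                bath=BathSpec(),
                ambient=sc.ambient,
                electrodes=bad,
            )

    def test_touching_patches_allowed(self):
        # geo1's cathode rim meets the anode radius: zero-measure contact
        build_scenario("geo1").validate()

    def test_single_potential_rejected(self):
        sc = build_scenario("geo1")
        same = tuple(
            ElectrodePatch(p.placement, p.r_in_mm, p.r_out_mm, 0.0,
                           interface=p.interface, name=p.name)
            for p in sc.electrodes
        )
        with pytest.raises(ScenarioError, match="distinct"):
            sc.with_overrides(electrodes=same)

    def test_patch_outside_cylinder_rejected(self):
        with pytest.raises(ScenarioError):
            build_scenario("geo1", {"pos_r_out": 12.0})


class TestSerialization:
    @pytest.mark.parametrize("name", SCENARIO_NAMES)
    def test_dict_round_trip_lossless(self, name):
        sc = build_scenario(name)
        assert scenario_from_dict(scenario_to_dict(sc)) == sc

    def test_yaml_round_trip_lossless(self, tmp_path):
        sc = build_scenario("geo4")
        path = tmp_path / "geo4.yaml"
        save_scenario(sc, path)
        assert load_scenario(path) == sc
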