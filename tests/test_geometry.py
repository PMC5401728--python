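"""Analytic geometry: cone profile, point classification, exact volumes."""

import math

import numpy as np
import pytest

from woundfield.geometry import (
    RegionLabel,
    SKIN_LAYER_LABELS,
    WoundSpec,
    classify_point,
    classify_points,
    layer_volume,
    wound_cavity_volume,
    wound_radius_at_depth,
)
from woundfield.scenarios import build_scenario


@pytest.fixture(scope="module")
def scenario():
    return build_scenario("endogenous")


class TestWoundCone:
    @pytest.mark.parametrize(
        "z, expected",
        [(0.0, 2.0), (5.514, 0.0), (2.757, 1.0), (0.014, 2.0 * (1 - 0.014 / 5.514))],
    )
    def test_linear_profile(self, z, expected):
        assert wound_radius_at_depth(z, WoundSpec()) == pytest.approx(expected)

    @pytest.mark.parametrize("z", [-0.1, 5.6])
    def test_outside_extent_raises(self, z):
        with pytest.raises(ValueError):
            wound_radius_at_depth(z, WoundSpec())


class TestClassification:
    @pytest.mark.parametrize(
        "r, z, label",
        [
            (5.0, 0.1, RegionLabel.epidermis),
            (0.0, 2.0, RegionLabel.wound_cavity),
            (5.0, -0.5, RegionLabel.bath),
            (5.0, 0.005, RegionLabel.stratum_corneum),
            (5.0, 1.0, RegionLabel.dermis),
            (5.0, 4.0, RegionLabel.subcutis),
            (11.0, 1.0, RegionLabel.outside),
            (5.0, -3.0, RegionLabel.outside),
        ],
    )
    def test_examples(self, scenario, r, z, label):
        assert classify_point(r, z, scenario) == label

    def test_cavity_takes_precedence_and_respects_cone(self, scenario):
        # just inside vs just outside the cone radius at depth 2 mm
        w = wound_radius_at_depth(2.0, scenario.wound)
        assert classify_point(w - 1e-6, 2.0, scenario) == RegionLabel.wound_cavity
        assert classify_point(w + 1e-6, 2.0, scenario) == RegionLabel.dermis

    def test_partition(self, scenario, rng):
        """Every sampled point gets exactly one valid label."""
        r = rng.uniform(0, 12, 5000)
        z = rng.uniform(-3, 6.5, 5000)
        labels = classify_points(r, z, scenario)
        assert set(np.unique(labels)) <= {int(l) for l in RegionLabel}


class TestVolumes:
    def test_layers_and_cavity_partition_the_cylinder(self, scenario):
        total = sum(layer_volume(l, scenario) for l in SKIN_LAYER_LABELS)
        total += wound_cavity_volume(scenario)
        expected = math.pi * 10.0**2 * 5.514
        assert total == pytest.approx(expected, rel=1e-12)

    def test_no_wound_gives_full_slab(self):
        sc = build_scenario("endogenous").with_overrides(wound=None)
        assert layer_volume(RegionLabel.dermis, sc) == pytest.approx(
            math.pi * 100 * 2.2
        )

    def test_monte_carlo_agrees_with_closed_form(self, scenario, rng):
        """MC estimate from classify_points matches the frustum formula."""
        n = 200_000
        r2 = rng.uniform(0, 100, n)  # uniform in r^2 => uniform in area
        z = rng.uniform(0, 5.514, n)
        labels = classify_points(np.sqrt(r2), z, scenario)
        box = math.pi * 100 * 5.514
        for label in (RegionLabel.dermis, RegionLabel.subcutis):
            mc = box * np.mean(labels == int(label))
            exact = layer_volume(label, scenario)
            assert mc == pytest.approx(exact, rel=0.02)

    def test_non_layer_label_rejected(self, scenario):
        with pytest.raises(ValueError):
            layer_volume(RegionLabel.bath, scenario)
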