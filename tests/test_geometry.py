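"""Angular primitives: growth angles, folding, entry zones, cortex distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from cometpol.geometry import (
    assign_origin_stack,
    build_entry_zone,
    distance_to_cortex,
    fold_angle,
    initial_growth_angle,
)
from cometpol.track_io import GolgiStack, NeuronGeometry

from conftest import make_track


def _rot(deg):
    r = np.radians(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


class TestInitialGrowthAngle:
    @pytest.mark.parametrize("direction,expected", [
        ((0.0, 1.0), 0.0),       # straight at the axon entry
        ((0.0, -1.0), 180.0),    # diametrically away
        ((1.0, 0.0), -90.0),     # rightward = clockwise = negative
        ((-1.0, 0.0), 90.0),
        ((1.0, 1.0), -45.0),
    ])
    def test_cardinal_directions(self, square_geometry, direction, expected):
        d = np.asarray(direction) / np.linalg.norm(direction)
        xy = [0.3 * i * d for i in range(3)]
        ga = initial_growth_angle(make_track(xy), square_geometry)
        assert ga.theta_signed == pytest.approx(expected, abs=1e-9)
        assert ga.theta_folded == pytest.approx(abs(expected), abs=1e-9)

    def test_origin_outside_soma_rejected(self, square_geometry):
        tr = make_track([[8, 8], [8, 8.5], [8, 9]])
        with pytest.raises(ValueError, match="outside"):
            initial_growth_angle(tr, square_geometry)

    def test_zero_displacement_rejected(self, square_geometry):
        tr = make_track([[1, 1], [1.3, 1], [1, 1]])  # returns to start
        with pytest.raises(ValueError, match="displacement"):
            initial_growth_angle(tr, square_geometry)

    def test_origin_stack_assignment(self, square_geometry):
        ga = initial_growth_angle(
            make_track([[1.2, 1.2], [1.2, 1.6], [1.2, 2.0]]), square_geometry)
        assert ga.origin_stack == "g1"
        ga2 = initial_growth_angle(
            make_track([[-3, -3], [-3, -2.6], [-3, -2.2]]), square_geometry)
        assert ga2.origin_stack is None

    @settings(deadline=None, max_examples=30)
    @given(phi=st.floats(-179.0, 179.0), rot=st.floats(-180.0, 180.0))
    def test_rotation_invariance(self, phi, rot):
        """Rotating geometry and track together leaves theta_signed unchanged."""
        d = np.array([np.sin(np.radians(phi)), np.cos(np.radians(phi))])
        base_xy = np.array([0.3 * i * d for i in range(3)])
        R = _rot(rot)
        soma = Polygon((np.array([(-5, -5), (5, -5), (5, 5), (-5, 5)]) @ R.T))
        geom = NeuronGeometry(soma=soma, axon_entry=R @ np.array([0.0, 5.0]),
                              dendrite_entries={}, frame_interval=5.0)
        ga = initial_growth_angle(make_track(base_xy @ R.T), geom)
        assert ga.theta_signed == pytest.approx(-phi, abs=1e-6)

    def test_mirror_negates_signed_angle(self, square_geometry):
        """Reflection across the origin-axon axis flips the sign only."""
        xy = np.array([[0.5, 0.5], [0.9, 0.8], [1.3, 1.1]]) - [0.5, 0.5]
        ga = initial_growth_angle(make_track(xy), square_geometry)
        mirrored = xy * np.array([-1.0, 1.0])  # axon axis is the y-axis
        gb = initial_growth_angle(make_track(mirrored), square_geometry)
        assert gb.theta_signed == pytest.approx(-ga.theta_signed, abs=1e-9)
        assert gb.theta_folded == pytest.approx(ga.theta_folded, abs=1e-9)


class TestFoldAngle:
    @pytest.mark.parametrize("x,expected", [(-135.0, 135.0), (0.0, 0.0),
                                            (180.0, 180.0), (-0.5, 0.5)])
    def test_examples(self, x, expected):
        assert fold_angle(x) == expected

    @given(st.floats(0.0, 180.0))
    def test_idempotent(self, x):
        assert fold_angle(fold_angle(x)) == fold_angle(x)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fold_angle(-180.0)
        with pytest.raises(ValueError):
            fold_angle(200.0)


class TestOriginStackTies:
    def test_nearest_wins_then_lexicographic(self):
        geom = NeuronGeometry(
            soma=Polygon([(-5, -5), (5, -5), (5, 5), (-5, 5)]),
            axon_entry=np.array([0.0, 5.0]), dendrite_entries={},
            golgi_stacks=(GolgiStack("b", np.array([0.5, 0.0]), 1.0),
                          GolgiStack("a", np.array([-0.7, 0.0]), 1.0)),
        )
        assert assign_origin_stack(np.array([0.2, 0.0]), geom) == "b"
        # exact tie: equidistant from both -> first name alphabetically
        assert assign_origin_stack(np.array([-0.1, 0.0]), geom) == "a"


class TestEntryZone:
    def test_square_top_edge(self, square_geometry):
        z = build_entry_zone(square_geometry, "axon", width=0.5)
        assert z.kind == "axon"
        assert np.allclose(z.inner_gate[:, 1], 4.75)
        assert np.allclose(z.outer_gate[:, 1], 5.25)
        assert np.allclose(z.outward_normal, [0, 1])

    def test_zero_width_rejected(self, square_geometry):
        with pytest.raises(ValueError):
            build_entry_zone(square_geometry, "axon", width=0.0)

    def test_circle_normal_matches_analytic(self):
        """On a circular soma the gate normal equals the radial direction."""
        n = 512
        th = np.arange(n) * 2 * np.pi / n
        r = 10.0 / np.cos(np.pi / n)  # vertices set so edge midpoints sit on r=10
        verts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        mid = (verts[5] + verts[6]) / 2.0
        geom = NeuronGeometry(soma=Polygon(verts), axon_entry=mid,
                              dendrite_entries={})
        z = build_entry_zone(geom, "axon")
        radial = mid / np.linalg.norm(mid)
        angle = np.arccos(np.clip(z.outward_normal @ radial, -1, 1))
        assert angle < 1e-6

    def test_caliber_clamped(self, square_geometry):
        z = build_entry_zone(square_geometry, "dendrite_1", caliber=20.0)
        assert np.linalg.norm(z.outer_gate[1] - z.outer_gate[0]) == pytest.approx(5.0)


class TestDistanceToCortex:
    def test_square_center_and_edge(self, square_geometry):
        assert distance_to_cortex([0, 0], square_geometry).soma == pytest.approx(5.0)
        assert distance_to_cortex([4.8, 0], square_geometry).soma == pytest.approx(0.2)

    def test_outside_rejected(self, square_geometry):
        with pytest.raises(ValueError):
            distance_to_cortex([6, 0], square_geometry)

    def test_matches_bruteforce_boundary_sampling(self):
        """Random interior points vs a dense boundary-sample oracle."""
        verts = [(-4, -3), (5, -4), (6, 2), (1, 5), (-5, 3)]
        geom = NeuronGeometry(soma=Polygon(verts), axon_entry=np.array([1.0, 5.0]),
                              dendrite_entries={})
        ring = geom.soma.exterior
        dense = np.array([ring.interpolate(s).coords[0]
                          for s in np.arange(0, ring.length, 5e-4)])
        rng = np.random.default_rng(42)
        tested = 0
        while tested < 25:
            p = rng.uniform([-5, -4], [6, 5])
            if not geom.soma.covers(Point(p)):
                continue
            tested += 1
            oracle = np.min(np.linalg.norm(dense - p, axis=1))
            assert distance_to_cortex(p, geom).soma == pytest.approx(oracle, abs=1e-3)
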