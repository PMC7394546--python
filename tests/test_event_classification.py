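"""Approach/entry scoring, turning detection, dendrite polarity, tabulation."""

import numpy as np
import pytest

from cometpol.event_classification import (
    CometEvents,
    TurningParams,
    classify_approach_entry,
    classify_dendrite_polarity,
    detect_turning,
    origin_in_zone,
    tabulate_events,
    validate_zones,
)
from cometpol.geometry import build_entry_zone

from conftest import make_track


@pytest.fixture
def zones(square_geometry):
    return [build_entry_zone(square_geometry, n)
            for n in square_geometry.neurite_names]


class TestApproachEntry:
    def test_stops_short_of_zone(self, square_geometry, zones):
        tr = make_track([[0, 0], [0, 1.5], [0, 3.0]])  # ends 1.75 μm from the band
        ae = classify_approach_entry(tr, zones, square_geometry)
        assert ae.approached is None and ae.entered is None

    def test_approach_without_entry(self, square_geometry, zones):
        tr = make_track([[0, 3.0], [0, 4.0], [0, 4.9]])  # terminates inside the band
        ae = classify_approach_entry(tr, zones, square_geometry)
        assert ae.approached == "axon" and ae.entered is None

    def test_full_entry(self, square_geometry, zones):
        tr = make_track([[0, 3.0], [0, 4.2], [0, 5.4], [0, 6.6]])
        ae = classify_approach_entry(tr, zones, square_geometry)
        assert ae.approached == "axon" and ae.entered == "axon"

    def test_dendrite_entry(self, square_geometry, zones):
        tr = make_track([[-2.5, -3.0], [-2.5, -4.2], [-2.5, -5.4], [-2.5, -6.6]])
        ae = classify_approach_entry(tr, zones, square_geometry)
        assert ae.entered == "dendrite_1"

    def test_touch_then_retreat_counts_both(self, square_geometry, zones):
        """A comet can approach two neurites but enter only one."""
        tr = make_track([[2.5, -3.5], [2.5, -4.8], [2.5, -3.5], [2.5, -2.0],
                         [1.2, 0.0], [0.5, 2.0], [0, 4.0], [0, 5.5], [0, 6.6]])
        ae = classify_approach_entry(tr, zones, square_geometry)
        assert ae.approached == "dendrite_2"
        assert set(ae.approached_all) == {"dendrite_2", "axon"}
        assert ae.entered == "axon"

    def test_origin_outside_soma_rejected(self, square_geometry, zones):
        tr = make_track([[0, 7], [0, 6], [0, 5.5]])
        with pytest.raises(ValueError, match="origin"):
            classify_approach_entry(tr, zones, square_geometry)

    def test_origin_in_zone_detected(self, square_geometry, zones):
        tr = make_track([[0, 4.9], [0, 4.0], [0, 3.0]])
        assert origin_in_zone(tr, zones) == "axon"
        tr2 = make_track([[0, 0], [0, 1], [0, 2]])
        assert origin_in_zone(tr2, zones) is None

    def test_overlapping_zones_rejected(self, square_geometry):
        a = build_entry_zone(square_geometry, "dendrite_1", caliber=5.0)
        b = build_entry_zone(square_geometry, "dendrite_2", caliber=5.0)
        with pytest.raises(ValueError, match="overlap"):
            validate_zones([a, b])


class TestDetectTurning:
    def test_straight_midsoma_qualifies_without_turn(self, square_geometry):
        xy = [[-2.5, 0.5 * i - 1.5] for i in range(10)]  # 4.5 μm straight
        q, t, c = detect_turning(make_track(xy), square_geometry)
        assert (q, t, c) == (True, False, False)

    def test_short_track_does_not_qualify(self, square_geometry):
        xy = [[0, -1.5 + 0.5 * i] for i in range(4)]  # 1.5 μm
        q, t, c = detect_turning(make_track(xy), square_geometry)
        assert (q, t) == (False, False)

    def test_right_angle_midsoma_turn(self, square_geometry):
        xy = [[-2.0 + 0.5 * i, -1.5] for i in range(5)]
        xy += [[0.0, -1.0 + 0.5 * (i + 1)] for i in range(5)]
        q, t, c = detect_turning(make_track(xy), square_geometry)
        assert (q, t, c) == (True, True, False)

    def test_turn_at_cortex_is_a_collision(self, square_geometry):
        """Direction changes within the cortex margin do not count as turns."""
        xy = [[-1.0, 0.8 * i - 2.0] for i in range(9)]  # straight up to y=4.4
        xy += [[-1.0 + 0.8 * (i + 1), 4.4] for i in range(3)]  # corner 0.6 from edge
        q, t, c = detect_turning(make_track(xy), square_geometry)
        assert q is True and t is False

    def test_below_threshold_angle_is_not_a_turn(self, square_geometry):
        xy = [[-1.0 + 0.5 * i, -1.0] for i in range(5)]
        d = np.array([np.cos(np.radians(30)), np.sin(np.radians(30))]) * 0.5
        last = np.array(xy[-1])
        xy += [(last + d * (i + 1)).tolist() for i in range(4)]
        q, t, c = detect_turning(make_track(xy), square_geometry)
        assert (q, t) == (True, False)

    def test_cortex_traveller_excluded(self, square_geometry):
        xy = [[-4.5, -3.0 + 0.5 * i] for i in range(12)]  # along the left edge
        q, t, c = detect_turning(make_track(xy), square_geometry)
        assert c is True and q is False

    def test_track_shorter_than_window(self, square_geometry):
        q, t, c = detect_turning(make_track([[0, 0], [0, 0.4]]), square_geometry)
        assert (q, t) == (False, False)


class TestDendritePolarity:
    def test_anterograde(self, square_geometry):
        xy = [[-2.5, -5.5 - 0.4 * i] for i in range(5)]
        pol = classify_dendrite_polarity(make_track(xy), square_geometry, "dendrite_1")
        assert pol == "anterograde"

    def test_retrograde(self, square_geometry):
        xy = [[-2.5, -7.5 + 0.4 * i] for i in range(5)]
        pol = classify_dendrite_polarity(make_track(xy), square_geometry, "dendrite_1")
        assert pol == "retrograde"

    def test_below_noise_floor_indeterminate(self, square_geometry):
        xy = [[-2.5, -6.0], [-2.5, -6.03], [-2.5, -6.05]]
        pol = classify_dendrite_polarity(make_track(xy), square_geometry, "dendrite_1")
        assert pol is None

    def test_never_in_segment_rejected(self, square_geometry):
        tr = make_track([[0, 0], [0, 0.5], [0, 1.0]])
        with pytest.raises(ValueError, match="segment"):
            classify_dendrite_polarity(tr, square_geometry, "dendrite_1")


class TestTabulate:
    def _event(self, i, **kw):
        return CometEvents(comet_id=f"c{i}", **kw)

    def test_counts_and_percentages(self):
        events = []
        i = 0
        for _ in range(3):  # approached + entered axon
            events.append(self._event(i, approached="axon", approached_all=("axon",),
                                      entered="axon")); i += 1
        for _ in range(2):  # approached axon only
            events.append(self._event(i, approached="axon",
                                      approached_all=("axon",))); i += 1
        for _ in range(1):  # approached dendrite only
            events.append(self._event(i, approached="dendrite_1",
                                      approached_all=("dendrite_1",))); i += 1
        for _ in range(4):  # no approach
            events.append(self._event(i)); i += 1
        df = tabulate_events(events).set_index("metric")
        assert df.loc["approached_axon", "k"] == 5
        assert df.loc["approached_axon", "n"] == 10
        assert df.loc["entered_axon_of_approached", "percent"] == pytest.approx(60.0)
        assert df.loc["entered_dendrite_of_approached", "percent"] == 0.0

    def test_empty_events_flagged(self):
        df = tabulate_events([])
        assert not df["defined"].any()
        assert (df["n"] == 0).all()

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CometEvents(comet_id="x", entered="axon")  # entered without approach
        with pytest.raises(ValueError):
            CometEvents(comet_id="x", turned=True)  # turned without qualifying


class TestConservationOnSimulatorOutput:
    def test_approach_counts_partition_soma_comets(self):
        """Approached-axon + approached-dendrite + no-approach = soma comets."""
        from cometpol.pipeline import RunConfig, classify_neuron
        from cometpol.synthetic_data import SimulationConfig, simulate_neuron
        geom, tracks, _ = simulate_neuron(SimulationConfig(seed=77, n_comets=80))
        events = classify_neuron(geom, tracks, RunConfig(conditions={}))
        soma = [e for e in events if e.origin_region == "soma"
                and not e.excluded_origin_in_zone]
        n_ax = sum("axon" in e.approached_all for e in soma)
        n_de = sum(any(a != "axon" for a in e.approached_all) for e in soma)
        n_none = sum(not e.approached_all for e in soma)
        assert n_ax + n_de + n_none == len(soma)
        for e in soma:  # entered is always a subset of approached
            if e.entered is not None:
                assert e.entered in e.approached_all
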