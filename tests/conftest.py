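import numpy as np
import pytest
from shapely.geometry import Polygon

from cometpol.track_io import CometTrack, GolgiStack, NeuronGeometry


def make_track(xy, comet_id="c1", movie_id="m1", dt=5.0, start_frame=1):
    xy = np.asarray(xy, dtype=float)
    t = (start_frame + np.arange(len(xy))) * dt
    return CometTrack(comet_id=comet_id, movie_id=movie_id,
                      points=np.column_stack([t, xy]),
                      present_at_first_frame=(start_frame == 0),
                      frame_interval=dt)


@pytest.fixture
def square_geometry():
    """10x10 square soma centred at the origin; axon entering mid-top edge,
    two dendrites on the bottom edge; one Golgi stack near the centre."""
    return NeuronGeometry(
        soma=Polygon([(-5, -5), (5, -5), (5, 5), (-5, 5)]),
        axon_entry=np.array([0.0, 5.0]),
        dendrite_entries={"dendrite_1": np.array([-2.5, -5.0]),
                          "dendrite_2": np.array([2.5, -5.0])},
        dendrite_branchpoints={"dendrite_1": np.array([-2.5, -12.0]),
                               "dendrite_2": np.array([2.5, -12.0])},
        golgi_stacks=(GolgiStack("g1", np.array([1.0, 1.0]), 1.0),),
        frame_interval=5.0,
    )
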