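import numpy as np
import pytest

from zebratrack.trajectory import Trajectory, arena_preset, zone_preset


@pytest.fixture
def novel_tank():
    return arena_preset("novel_tank")


@pytest.fixture
def novel_tank_zones():
    return zone_preset("novel_tank")


@pytest.fixture
def mirror_zones():
    return zone_preset("mirror")


@pytest.fixture
def cs_es_zones():
    return zone_preset("social_preference")


def make_traj(xy, fps=25.0, video_id="v", fish_id="f"):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(
        video_id=video_id,
        fish_id=fish_id,
        fps=fps,
        frames=np.arange(len(xy)),
        xy=xy,
    )


@pytest.fixture
def make_trajectory():
    return make_traj
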