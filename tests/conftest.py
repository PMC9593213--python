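import numpy as np
import pytest

from neutromig.imaging import Detection, Trajectory


def make_traj(positions, frame_interval=10.0, frames=None, track_id=0):
    """Build a Trajectory from an (n, 2) position array (um)."""
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    dets = [
        Detection(frame=int(f), x_um=float(x), y_um=float(y), area_um2=np.nan,
                  label=track_id)
        for f, (x, y) in zip(frames, positions)
    ]
    return Trajectory(track_id=track_id, detections=dets,
                      frame_interval=frame_interval)


@pytest.fixture
def traj_factory():
    return make_traj


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
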