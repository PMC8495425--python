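import numpy as np
import pytest

from trackdiff.core import AcquisitionParams, Trajectory


@pytest.fixture
def acq():
    """Canonical acquisition: 33 ms frames, continuous illumination, 160 nm px."""
    return AcquisitionParams(
        frame_interval=0.033, exposure=0.033, pixel_size=0.16, blur_coefficient=1 / 6
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_track(positions, track_id="t0", frames=None, intensities=None):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Trajectory(
        track_id=track_id, frames=frames, positions=positions, intensities=intensities
    )


@pytest.fixture
def make_trajectory():
    return make_track
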