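import warnings

import numpy as np
import pytest

from nbdyn.core import AcquisitionConfig, Movie

# the missing-reference warning from FRAP extraction is exercised on
# purpose in several tests
warnings.filterwarnings("ignore", message="no reference ROI given")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def make_uniform_movie(values, frame_shape=(16, 16), frame_time=0.121, timestamps=None):
    """Movie whose every pixel carries the given per-frame value."""
    values = np.asarray(values, dtype=float)
    frames = np.broadcast_to(
        values[:, None, None], (len(values),) + frame_shape
    ).copy()
    acq = AcquisitionConfig(
        n_frames=len(values), frame_shape=frame_shape, frame_time=frame_time
    )
    return Movie(frames, acq, timestamps=timestamps)


@pytest.fixture(scope="session")
def small_control_movie():
    """A reduced control-preset acquisition shared by read-only tests."""
    from nbdyn.simulate import simulate_droplet_movie

    acq = AcquisitionConfig(n_frames=240)
    movie, truth = simulate_droplet_movie(acq=acq, n_particles=1500, seed=101)
    return movie, truth
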