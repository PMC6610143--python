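import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from livespot import synth

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def noiseless_optics() -> synth.Optics:
    """Small field, no shot/read noise (pair with render_movie(shot_noise=False))."""
    return synth.Optics(
        photons_per_spot=100.0,
        background_level=10.0,
        read_noise_sd=0.0,
        field_px=(40, 40),
        pixel_size_um=0.13,
    )


@pytest.fixture
def single_spot_movie(noiseless_optics):
    """One stationary emitter at (20.0, 30.0) px, rendered without noise."""
    px = noiseless_optics.pixel_size_um
    tracks = pd.DataFrame(
        {
            "track_id": [0],
            "frame": [0],
            "x_um": [20.0 * px],
            "y_um": [30.0 * px],
            "channel": [0],
            "state": ["bound"],
        }
    )
    return synth.render_movie(tracks, noiseless_optics, shot_noise=False), (20.0, 30.0)


def stationary_grid_tracks(optics: synth.Optics, n_frames: int, jitter_px: float = 2.0, seed: int = 7):
    """A well-separated grid of stationary emitters covering the field."""
    h, w = optics.field_px
    gx, gy = np.meshgrid(np.arange(12, w - 4, 17), np.arange(12, h - 4, 17))
    rng = np.random.default_rng(seed)
    pos = np.c_[gx.ravel(), gy.ravel()] + rng.uniform(-jitter_px, jitter_px, (gx.size, 2))
    rows = [
        (i, t, x * optics.pixel_size_um, y * optics.pixel_size_um, 0, "bound")
        for i, (x, y) in enumerate(pos)
        for t in range(n_frames)
    ]
    return pd.DataFrame(rows, columns=synth.TRACK_COLUMNS), pos
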