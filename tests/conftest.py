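import numpy as np
import pytest

from leukowalk.tracks import Track, TrackDataset


def make_track(points, dt=30.0, track_id="t0"):
    return Track(track_id, np.asarray(points, dtype=float), dt)


@pytest.fixture
def straight_track():
    """Constant-velocity straight line along x: 5 points, 6 µm steps, dt 30 s."""
    pts = np.zeros((5, 3))
    pts[:, 0] = np.arange(5) * 6.0
    return make_track(pts)


@pytest.fixture
def zigzag_track():
    """Alternating exact reversals along x (1 µm amplitude), dt 30 s."""
    pts = np.zeros((6, 3))
    pts[:, 0] = [0, 1, 0, 1, 0, 1]
    return make_track(pts)


@pytest.fixture
def brownian_dataset():
    """200 discrete-time Brownian tracks (independent Gaussian steps)."""
    rng = np.random.default_rng(1234)
    tracks = [
        Track(f"b{i}", np.cumsum(rng.normal(0, 2.0, size=(20, 3)), axis=0), 30.0)
        for i in range(200)
    ]
    return TrackDataset(tracks, label="brownian-oracle")
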