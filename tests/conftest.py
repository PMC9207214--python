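import numpy as np
import pytest

from olcquant.tracks import Track


def make_track(points, dt=5.0, track_id="t0", **annotations) -> Track:
    """Build a Track from bare (x, y) points on an even time grid."""
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) * dt
    return Track(track_id=track_id, t=t, xy=pts, **annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
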