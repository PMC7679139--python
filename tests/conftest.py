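import numpy as np
import pytest

from asymtrack.io_tracks import EndEvent, Fate, Track


def make_track(depths, t=None, dt=5.0, track_id="t1", pair_id=None, fate=Fate.UNKNOWN, **kw):
    depths = np.asarray(depths, dtype=float)
    if t is None:
        t = np.arange(len(depths)) * dt
    return Track(
        track_id=track_id,
        embryo_id=kw.pop("embryo_id", "E1"),
        pair_id=pair_id,
        fate=fate,
        t=np.asarray(t, dtype=float),
        depth=depths,
        **kw,
    )


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_piecewise_track(rng, n_max=30, depth_max=60.0, track_id="pl"):
    """Random piecewise-linear depth trajectory on a jittered grid (test-local)."""
    n = int(rng.integers(3, n_max + 1))
    t = np.concatenate([[0.0], np.cumsum(rng.uniform(1.0, 8.0, size=n - 1))])
    depth = rng.uniform(0.0, depth_max, size=n)
    return make_track(depth, t=t, track_id=track_id)
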