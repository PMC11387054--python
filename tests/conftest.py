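import numpy as np
import pytest

import wakeflight as wf


@pytest.fixture(scope="session")
def small_flock():
    """A tiny flock (4 birds, 60 s): fast, for structural tests."""
    return wf.simulate_flock(wf.SimConfig(n_birds=4, duration_s=60.0, seed=5))


@pytest.fixture(scope="session")
def flock600():
    """One 10-minute flight of 3 birds: long enough for alignment tests."""
    return wf.simulate_flock(wf.SimConfig(n_birds=3, duration_s=600.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def straight_tracks(n_birds=2, n=300, rate=5.0, speed=12.0, spacing=(-2.0, 0.0, 0.0)):
    """Parallel straight northbound tracks with constant spacing."""
    dt = 1.0 / rate
    t = np.arange(n) * dt
    tracks = {}
    for b in range(n_birds):
        off = np.array(spacing) * b
        pos = np.column_stack([
            np.full(n, off[0] * 0 + off[1]),   # east offset from dy
            speed * t + b * spacing[0],        # north: staggered behind
            100.0 + np.full(n, off[2]),
        ])
        vel = np.column_stack([np.zeros(n), np.full(n, speed), np.zeros(n)])
        tracks[b] = {"t": t, "position": pos, "velocity": vel,
                     "valid": np.ones(n, bool)}
    return tracks
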