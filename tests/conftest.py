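"""Shared fixtures: grids, planar phase fields, short synthetic recordings."""

import numpy as np
import pytest

import gridwave as gw


@pytest.fixture(scope="session")
def grid():
    """The standard 4 x 8 microgrid at 2 mm pitch."""
    return gw.make_grid(4, 8, 2.0)


def planar_phases(geometry, direction_deg, k_deg_mm, offset_rad=0.0):
    """Exact plane-wave phase field: phi_i = offset - k_rad * proj_i(direction)."""
    th = np.deg2rad(direction_deg)
    k_rad = k_deg_mm * np.pi / 180.0
    proj = geometry.coords @ np.array([np.cos(th), np.sin(th)])
    return np.angle(np.exp(1j * (offset_rad - k_rad * proj)))


@pytest.fixture(scope="session")
def bidirectional_recording(grid):
    """20 s at 256 Hz: 6 Hz plane waves alternating 30/210 deg in 2 s segments."""
    c1 = gw.WaveComponent(center_freq=6.0, direction=30.0, spatial_freq=15.0,
                          amplitude=10.0)
    c2 = gw.WaveComponent(center_freq=6.0, direction=210.0, spatial_freq=15.0,
                          amplitude=10.0)
    segs = tuple((2.0 * i, 2.0 * (i + 1), (i % 2,)) for i in range(10))
    rec = gw.synthesize(grid, [c1, c2], gw.RegimeSchedule(segments=segs),
                        noise_sd=3.0, duration_s=20.0, fs=256.0, seed=3)
    planted = {"freq": 6.0, "k": 15.0, "dirs": (30.0, 210.0), "segment_s": 2.0}
    return rec, planted


@pytest.fixture(scope="session")
def bidirectional_fits(bidirectional_recording, grid):
    """Wave-fit series for the bidirectional fixture (200-iteration nulls)."""
    rec, planted = bidirectional_recording
    band = gw.extract_band(rec, planted["freq"], fs_analysis=30.0)
    fits = gw.fit_series(band, grid, null_iters=200, ci_percent=99.0, seed=4)
    return fits, band, planted


def planted_directions(t, planted):
    """Ground-truth direction at each time for the alternating schedule."""
    seg = planted["segment_s"]
    idx = (t // seg).astype(int) % 2
    return np.where(idx == 0, planted["dirs"][0], planted["dirs"][1])
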