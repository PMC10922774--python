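import math

import numpy as np
import pytest

from larvascreen import PlateGeometry, PoseTrack, build_default_schedule
from larvascreen.simulate import EYE_SEPARATION_MM, YOLK_OFFSET_MM


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


@pytest.fixture(scope="session")
def geom():
    return PlateGeometry()


def _coords_from_pose(positions, headings_deg):
    """Body-point coordinates for given eye-midpoint positions and headings."""
    pos = np.asarray(positions, dtype=float)
    th = np.radians(np.asarray(headings_deg, dtype=float))
    hx, hy = np.cos(th), np.sin(th)
    px, py = hy, -hx  # right-hand perpendicular in the y-up frame
    n = len(pos)
    coords = np.empty((n, 3, 2))
    coords[:, 0, 0] = pos[:, 0] + 0.5 * EYE_SEPARATION_MM * px
    coords[:, 0, 1] = pos[:, 1] + 0.5 * EYE_SEPARATION_MM * py
    coords[:, 1, 0] = pos[:, 0] - 0.5 * EYE_SEPARATION_MM * px
    coords[:, 1, 1] = pos[:, 1] - 0.5 * EYE_SEPARATION_MM * py
    coords[:, 2, 0] = pos[:, 0] - YOLK_OFFSET_MM * hx
    coords[:, 2, 1] = pos[:, 1] - YOLK_OFFSET_MM * hy
    return coords


@pytest.fixture
def make_track(geom):
    """Factory for hand-crafted pose tracks: give eye-midpoint positions
    (relative to the well center) and headings; likelihoods default to 1."""

    def _make(positions, headings_deg, well="A1", likelihood=None, dt=6.0):
        cx, cy = geom.center(well)
        pos = np.asarray(positions, dtype=float) + np.array([cx, cy])
        coords = _coords_from_pose(pos, headings_deg)
        n = len(pos)
        lik = np.ones((n, 3)) if likelihood is None else np.asarray(likelihood, float)
        return PoseTrack(
            well_id=well,
            time_s=np.arange(n) * dt,
            coords=coords,
            likelihood=lik,
        )

    return _make


@pytest.fixture
def full_session_track(make_track, schedule):
    """A deterministic full-session track: alternating scoot steps along
    +x with heading 90 deg, confined near the well center."""

    def _make(well="A1", heading=90.0):
        n = schedule.n_frames
        xs = 0.25 * ((np.arange(n) % 2) - 0.5)  # hop between two points, 0.25 mm apart
        positions = np.stack([xs, np.zeros(n)], axis=1)
        return make_track(positions, np.full(n, heading), well=well)

    return _make
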