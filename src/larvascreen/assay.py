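"""Temporal structure of the behavioral assay and 96-well plate geometry.

The assay is a 3-hour session recorded at one frame every 6 s and analyzed
in eighteen contiguous 10-minute *periods*.  Periods 1-6 present no
stimulus, periods 7-14 present moving lines (color changing every two
periods, direction alternating 180 deg every period, the last two periods
at a faster line speed), period 15 is again stimulus-free and periods
16-18 deliver acoustic stimuli repeating at 20- or 1-second intervals.

Every other module consumes the schedule and geometry defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

PERIOD_S = 600.0
N_PERIODS = 18
SESSION_S = PERIOD_S * N_PERIODS

KIND_NONE = "none"
KIND_LINES = "moving_lines"
KIND_ACOUSTIC = "acoustic"

#: (color, speed) of the eight moving-line periods 7..14, in order.
LINE_LAYOUT = (
    ("red", "normal"), ("red", "normal"),
    ("green", "normal"), ("green", "normal"),
    ("blue", "normal"), ("blue", "normal"),
    ("red", "fast"), ("red", "fast"),
)


@dataclass(frozen=True)
class Period:
    """One 10-minute assay interval with its stimulus attributes.

    ``motion_direction_deg`` and ``acoustic_interval_s`` are ``None``
    when the attribute does not apply to the period's stimulus kind.
    """

    index: int
    kind: str
    color: str | None = None
    speed: str | None = None
    motion_direction_deg: float | None = None
    acoustic_interval_s: float | None = None

    @property
    def start_s(self) -> float:
        return (self.index - 1) * PERIOD_S

    @property
    def end_s(self) -> float:
        return self.index * PERIOD_S

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_PERIODS:
            raise ValueError(f"period index {self.index} outside 1..{N_PERIODS}")
        if self.kind not in (KIND_NONE, KIND_LINES, KIND_ACOUSTIC):
            raise ValueError(f"unknown period kind {self.kind!r}")
        if self.kind == KIND_LINES:
            if self.motion_direction_deg is None or self.color is None:
                raise ValueError(f"period {self.index}: moving-line periods need color and direction")
        if self.kind == KIND_ACOUSTIC and self.acoustic_interval_s not in (1.0, 20.0):
            raise ValueError(f"period {self.index}: acoustic interval must be 1 or 20 s")


@dataclass
class StimulusSchedule:
    """The ordered 18-period assay structure."""

    periods: list[Period]
    frame_interval_s: float = 6.0
    session_length_s: float = SESSION_S

    def __post_init__(self) -> None:
        if len(self.periods) != N_PERIODS:
            raise ValueError(f"schedule needs {N_PERIODS} periods, got {len(self.periods)}")
        for i, p in enumerate(self.periods, start=1):
            if p.index != i:
                raise ValueError(f"period at position {i} has index {p.index}")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length_s / self.frame_interval_s))

    def period_of(self, t: float) -> Period:
        """Return the period whose half-open interval [start, start+600) holds ``t``."""
        if not 0 <= t < self.session_length_s:
            raise ValueError(f"time {t} s outside session [0, {self.session_length_s})")
        return self.periods[int(t // PERIOD_S)]

    def periods_of_kind(self, kind: str) -> list[Period]:
        return [p for p in self.periods if p.kind == kind]

    def line_periods(self, color: str | None = None, speed: str | None = None) -> list[Period]:
        out = self.periods_of_kind(KIND_LINES)
        if color is not None:
            out = [p for p in out if p.color == color]
        if speed is not None:
            out = [p for p in out if p.speed == speed]
        return out

    def acoustic_periods(self, interval_s: float | None = None) -> list[Period]:
        out = self.periods_of_kind(KIND_ACOUSTIC)
        if interval_s is not None:
            out = [p for p in out if p.acoustic_interval_s == interval_s]
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frame_interval_s": self.frame_interval_s,
            "session_length_s": self.session_length_s,
            "periods": {
                p.index: {
                    "kind": p.kind,
                    "color": p.color,
                    "speed": p.speed,
                    "motion_direction_deg": p.motion_direction_deg,
                    "acoustic_interval_s": p.acoustic_interval_s,
                }
                for p in self.periods
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        periods = [
            Period(index=i, **d["periods"][i]) for i in sorted(d["periods"])
        ]
        return cls(
            periods=periods,
            frame_interval_s=d.get("frame_interval_s", 6.0),
            session_length_s=d.get("session_length_s", SESSION_S),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StimulusSchedule":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_default_schedule(
    acoustic_intervals: tuple[float, float, float] = (20.0, 1.0, 20.0),
    base_direction_deg: float = 0.0,
) -> StimulusSchedule:
    """Construct the default 18-period schedule.

    Line motion is horizontal by default, alternating 180 deg between
    consecutive line periods.  The acoustic block defaults to
    (20 s, 1 s, 20 s) inter-stimulus intervals so habituation can be read
    as the first-versus-last response to the sparse (20 s) stimulus.
    """
    periods: list[Period] = []
    for i in range(1, 7):
        periods.append(Period(index=i, kind=KIND_NONE))
    for j, (color, speed) in enumerate(LINE_LAYOUT):
        periods.append(
            Period(
                index=7 + j,
                kind=KIND_LINES,
                color=color,
                speed=speed,
                motion_direction_deg=(base_direction_deg + 180.0 * (j % 2)) % 360.0,
            )
        )
    periods.append(Period(index=15, kind=KIND_NONE))
    for j, iv in enumerate(acoustic_intervals):
        periods.append(Period(index=16 + j, kind=KIND_ACOUSTIC, acoustic_interval_s=float(iv)))
    return StimulusSchedule(periods=periods)


# ---------------------------------------------------------------------------
# Plate geometry
# ---------------------------------------------------------------------------

ROWS = "ABCDEFGH"
N_COLS = 12


def well_ids() -> list[str]:
    """All 96 well IDs A1..H12 in row-major order."""
    return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]


@dataclass
class PlateGeometry:
    """96-well plate layout: 8 rows x 12 columns on a 9 mm pitch.

    Coordinates are mm in a y-up frame ("up" points away from the bottom
    edge of the image); row A is the top row.
    """

    well_radius_mm: float = 3.2
    pitch_mm: float = 9.0
    well_centers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.well_centers:
            for ri, r in enumerate(ROWS):
                for c in range(1, N_COLS + 1):
                    x = (c - 1) * self.pitch_mm
                    y = (len(ROWS) - 1 - ri) * self.pitch_mm  # row A on top, y-up
                    self.well_centers[f"{r}{c}"] = (x, y)
        if self.pitch_mm < 2 * self.well_radius_mm:
            raise ValueError("wells overlap: pitch < 2 x well radius")

    def center(self, well_id: str) -> tuple[float, float]:
        """Center of a well; plate-qualified IDs like ``p2_G11`` resolve
        to their within-plate position."""
        key = well_id.rsplit("_", 1)[-1]
        try:
            return self.well_centers[key]
        except KeyError:
            raise KeyError(f"unknown well {well_id!r}") from None

    def to_dict(self) -> dict:
        return {
            "well_radius_mm": self.well_radius_mm,
            "pitch_mm": self.pitch_mm,
            "well_centers": {w: list(c) for w, c in self.well_centers.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateGeometry":
        return cls(
            well_radius_mm=d["well_radius_mm"],
            pitch_mm=d.get("pitch_mm", 9.0),
            well_centers={w: tuple(c) for w, c in d["well_centers"].items()},
        )


def polar_in_well(
    p: tuple[float, float], well: str, geom: PlateGeometry
) -> tuple[float, float]:
    """Polar coordinates of a point relative to its well center.

    Returns ``(r_frac, theta_deg)`` where ``r_frac`` is distance from the
    well center as a fraction of the well radius and ``theta_deg`` is
    measured counterclockwise from +x in the y-up frame, in [0, 360).
    The center maps to (0, 0) by convention.
    """
    cx, cy = geom.center(well)
    dx, dy = p[0] - cx, p[1] - cy
    r = math.hypot(dx, dy) / geom.well_radius_mm
    if r == 0.0:
        return 0.0, 0.0
    theta = math.degrees(math.atan2(dy, dx)) % 360.0
    return r, theta


def wrap_angle_deg(a: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def circular_diff_deg(a: float, b: float) -> float:
    """Absolute circular difference |a - b| in [0, 180]."""
    return abs(wrap_angle_deg(a - b))
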