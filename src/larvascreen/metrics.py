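"""From pose tracks to the 25-measure behavioral vector.

A larva is tracked as three body points (right eye, left eye, yolk sac)
per 6-s frame.  Kinematics reduce each frame to a position (the eye
midpoint), a heading (the yolk-to-eye-midpoint direction) and, per frame
transition, a displacement classed as rest / scoot / burst and a signed
heading change.  Per-period summaries of those quantities are then
combined into the canonical 25-behavior vector: overall activity,
acoustic reactivity (habituation, startle, excitability), movement
classes, edge preference (thigmotaxis), turning, optomotor alignment
with moving lines, and upward orientation.

Quality control follows the screen's rules: body points below a
likelihood of 0.5 are discarded, and larvae that moved in fewer than 1%
of frame transitions are excluded altogether.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .assay import (
    KIND_LINES,
    PlateGeometry,
    StimulusSchedule,
    circular_diff_deg,
)

if TYPE_CHECKING:  # pragma: no cover
    from .pose_io import PoseTrack

#: Canonical behavior names, in order 1..25.  These strings are the
#: column headers of every per-larva table and profile matrix.
BEHAVIOR_NAMES: tuple[str, ...] = (
    "Activity during the 1st hour",
    "Activity during Period 15",
    "Habituation",
    "Startle response",
    "Excitability",
    "Optomotor response to moving red lines",
    "Optomotor response to moving green lines",
    "Optomotor response to moving blue lines",
    "Optomotor response to faster moving red lines",
    "Combined optomotor response to red, green, and blue moving lines",
    "Scoot movement during the 1st hour",
    "Scoot movement during the presentation of moving lines of any color or speed",
    "Burst movement during the first hour",
    "Burst movement during the presentation of moving lines of any color or speed",
    "Percent edge location during the first hour",
    "Percent edge location during the presentation of moving lines of any color or speed",
    "Percent clockwise orientation during the 1st hour",
    "Percent clockwise orientation during the presentation of moving lines of any color or speed",
    "Upward orientation during moving red lines",
    "Upward orientation during moving green lines",
    "Upward orientation during moving blue lines",
    "Upward orientation during faster moving red lines",
    "Combined upward orientation during red, green, and blue moving lines",
    "Turn angle during the 1st hour",
    "Absolute turn angle during the 1st hour",
)

N_BEHAVIORS = len(BEHAVIOR_NAMES)

# movement class codes on frame transitions
REST, SCOOT, BURST = 0, 1, 2

SUMMARY_COLUMNS = (
    "activity", "scoot", "burst", "edge", "clockwise",
    "omr", "up", "turn", "abs_turn", "valid_frac",
)


class InsufficientDataError(ValueError):
    pass


@dataclass
class QCConfig:
    """Quality-control thresholds.

    min_likelihood
        Body-point likelihood below which a frame is discarded (default
        0.50, the screen's filter).
    min_move_fraction
        Larvae moving in fewer than this fraction of transitions over
        the whole session are excluded (default 0.01, i.e. 1%).
    min_valid_frame_fraction_per_period
        A period's summary is missing when fewer than this fraction of
        its frames survive the likelihood filter.
    """

    min_likelihood: float = 0.50
    min_move_fraction: float = 0.01
    min_valid_frame_fraction_per_period: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_likelihood", "min_move_fraction",
                     "min_valid_frame_fraction_per_period"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class MovementThresholds:
    """Displacement cut-offs (mm per 6-s transition) separating rest,
    scoot and burst movement classes."""

    d_move_mm: float = 0.15
    d_burst_mm: float = 1.0
    #: r_frac beyond which a larva counts as edge-located
    edge_frac: float = 0.67
    #: half-width of the alignment cone for optomotor / upward orientation
    align_cone_deg: float = 45.0

    def __post_init__(self) -> None:
        if not 0 < self.d_move_mm < self.d_burst_mm:
            raise ValueError("need 0 < d_move_mm < d_burst_mm")


@dataclass
class KinematicsTrack:
    """Frame-level kinematics for one larva.

    Per frame: position (eye midpoint, mm), heading (deg, yolk-to-eyes,
    NaN when any body point fails the likelihood filter), validity flag,
    radial position as a fraction of the well radius, and the sign of
    cross(center->position, heading) which is negative for clockwise
    orientation in the y-up frame.  Per transition (between adjacent
    valid frames): displacement (mm), movement class, signed heading
    change in (-180, 180].
    """

    well_id: str
    time_s: np.ndarray
    position: np.ndarray          # (n, 2)
    heading_deg: np.ndarray       # (n,) NaN when undefined
    valid: np.ndarray             # (n,) bool
    r_frac: np.ndarray            # (n,) NaN when invalid
    cw_sign: np.ndarray           # (n,) -1 cw, +1 ccw, 0 degenerate, NaN invalid
    displacement_mm: np.ndarray   # (n-1,) NaN when either endpoint invalid
    movement_class: np.ndarray    # (n-1,) int code, -1 when undefined
    dheading_deg: np.ndarray      # (n-1,) NaN when undefined

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


def derive_kinematics(
    track: "PoseTrack",
    geom: PlateGeometry,
    qc: QCConfig | None = None,
    thr: MovementThresholds | None = None,
) -> KinematicsTrack:
    """Reduce a three-point pose track to positions, headings and
    movement classes.

    Frames where any body point's likelihood falls below
    ``qc.min_likelihood`` are invalid and excluded from every aggregate;
    displacements and heading changes are defined only between adjacent
    valid frames.
    """
    qc = qc or QCConfig()
    thr = thr or MovementThresholds()
    n = len(track.time_s)
    if n < 2:
        raise InsufficientDataError(
            f"track {track.well_id}: need at least 2 frames, got {n}"
        )

    lik = track.likelihood
    coords = track.coords  # (n, 3, 2): right eye, left eye, yolk
    valid = np.all(lik >= qc.min_likelihood, axis=1) & np.all(
        np.isfinite(coords.reshape(n, -1)), axis=1
    )

    mid = 0.5 * (coords[:, 0, :] + coords[:, 1, :])  # eye midpoint
    vec = mid - coords[:, 2, :]                      # yolk -> eyes
    heading = np.degrees(np.arctan2(vec[:, 1], vec[:, 0])) % 360.0
    degenerate = np.hypot(vec[:, 0], vec[:, 1]) == 0.0
    heading[~valid | degenerate] = np.nan

    cx, cy = geom.center(track.well_id)
    rel = mid - np.array([cx, cy])
    r_frac = np.hypot(rel[:, 0], rel[:, 1]) / geom.well_radius_mm
    r_frac[~valid] = np.nan

    # cross(center->position, heading unit vector); negative = clockwise
    hx = np.cos(np.radians(heading))
    hy = np.sin(np.radians(heading))
    cross = rel[:, 0] * hy - rel[:, 1] * hx
    cw_sign = np.sign(cross)
    cw_sign[~valid | np.isnan(heading)] = np.nan

    pair_ok = valid[:-1] & valid[1:]
    disp = np.hypot(*(mid[1:] - mid[:-1]).T)
    disp[~pair_ok] = np.nan

    mclass = np.full(n - 1, -1, dtype=int)
    ok = pair_ok
    mclass[ok & (disp < thr.d_move_mm)] = REST
    mclass[ok & (disp >= thr.d_move_mm) & (disp < thr.d_burst_mm)] = SCOOT
    mclass[ok & (disp >= thr.d_burst_mm)] = BURST

    dh = heading[1:] - heading[:-1]
    dh = (dh + 180.0) % 360.0 - 180.0
    dh[dh == -180.0] = 180.0
    dh[~pair_ok] = np.nan

    return KinematicsTrack(
        well_id=track.well_id,
        time_s=np.asarray(track.time_s, dtype=float),
        position=mid,
        heading_deg=heading,
        valid=valid,
        r_frac=r_frac,
        cw_sign=cw_sign,
        displacement_mm=disp,
        movement_class=mclass,
        dheading_deg=dh,
    )


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else np.nan


def period_summaries(
    kin: KinematicsTrack,
    schedule: StimulusSchedule,
    qc: QCConfig | None = None,
    thr: MovementThresholds | None = None,
) -> pd.DataFrame:
    """Per-period behavioral summaries for one larva.

    Returns a DataFrame indexed by period 1..18 with columns
    ``activity, scoot, burst, edge, clockwise, omr, up`` (percentages),
    ``turn, abs_turn`` (degrees) and ``valid_frac``.  Transition-level
    quantities are attributed to the period containing the transition's
    first frame.  A period with fewer valid frames than
    ``min_valid_frame_fraction_per_period`` is reported missing (NaN).
    """
    qc = qc or QCConfig()
    thr = thr or MovementThresholds()
    n = kin.n_frames
    expected = schedule.n_frames
    if abs(n - expected) > 1:
        raise ValueError(
            f"track {kin.well_id}: {n} frames but schedule implies {expected}"
        )

    frame_period = np.array(
        [schedule.period_of(t).index for t in kin.time_s], dtype=int
    )
    rows = []
    for p in schedule.periods:
        m = frame_period == p.index
        mt = m[:-1]  # transitions starting in this period
        n_frames_p = int(m.sum())
        n_valid = int((m & kin.valid).sum())
        row: dict[str, float] = {"period": p.index}
        if n_frames_p == 0 or n_valid < qc.min_valid_frame_fraction_per_period * n_frames_p:
            for c in SUMMARY_COLUMNS[:-1]:
                row[c] = np.nan
            row["valid_frac"] = _pct(n_valid, n_frames_p) / 100.0 if n_frames_p else np.nan
            rows.append(row)
            continue
        row["valid_frac"] = n_valid / n_frames_p

        cls = kin.movement_class[mt]
        defined = cls >= 0
        n_tr = int(defined.sum())
        row["activity"] = _pct(int(((cls == SCOOT) | (cls == BURST)).sum()), n_tr)
        row["scoot"] = _pct(int((cls == SCOOT).sum()), n_tr)
        row["burst"] = _pct(int((cls == BURST).sum()), n_tr)

        r = kin.r_frac[m]
        r_ok = np.isfinite(r)
        row["edge"] = _pct(int((r[r_ok] > thr.edge_frac).sum()), int(r_ok.sum()))

        cw = kin.cw_sign[m]
        n_cw = int((cw == -1).sum())
        n_ccw = int((cw == 1).sum())
        row["clockwise"] = _pct(n_cw, n_cw + n_ccw)

        h = kin.heading_deg[m]
        h_ok = np.isfinite(h)
        if p.kind == KIND_LINES:
            d = np.array(
                [circular_diff_deg(a, p.motion_direction_deg) for a in h[h_ok]]
            )
            row["omr"] = _pct(int((d <= thr.align_cone_deg).sum()), int(h_ok.sum()))
        else:
            row["omr"] = np.nan
        du = np.array([circular_diff_deg(a, 90.0) for a in h[h_ok]])
        row["up"] = _pct(int((du <= thr.align_cone_deg).sum()), int(h_ok.sum()))

        dh = kin.dheading_deg[mt]
        dh = dh[np.isfinite(dh)]
        row["turn"] = float(np.mean(dh)) if dh.size else np.nan
        row["abs_turn"] = float(np.mean(np.abs(dh))) if dh.size else np.nan
        rows.append(row)

    return pd.DataFrame(rows).set_index("period")


def _mean_over(summ: pd.DataFrame, col: str, periods: Iterable[int]) -> float:
    vals = summ.loc[list(periods), col].to_numpy(dtype=float)
    if np.all(np.isnan(vals)):
        return np.nan
    return float(np.nanmean(vals))


def behavior_vector(
    summaries: pd.DataFrame, schedule: StimulusSchedule
) -> pd.Series:
    """Combine 18 per-period summaries into the 25-behavior vector.

    Acoustic contrasts use simple activity differences: habituation is
    the first minus the last sparse-stimulus (20 s interval) period,
    startle is the first sparse-stimulus period minus the stimulus-free
    period 15, excitability is the dense-stimulus (1 s interval) period
    minus period 15.  A behavior whose every component period is missing
    is reported missing, never zero.
    """
    base = [p.index for p in schedule.periods[:6] if p.kind == "none"]
    p15 = 15
    sparse = [p.index for p in schedule.acoustic_periods(20.0)]
    dense = [p.index for p in schedule.acoustic_periods(1.0)]
    red = [p.index for p in schedule.line_periods("red", "normal")]
    green = [p.index for p in schedule.line_periods("green", "normal")]
    blue = [p.index for p in schedule.line_periods("blue", "normal")]
    fast = [p.index for p in schedule.line_periods("red", "fast")]
    lines = [p.index for p in schedule.periods_of_kind(KIND_LINES)]

    act = lambda ps: _mean_over(summaries, "activity", ps)  # noqa: E731

    b: dict[int, float] = {}
    b[1] = act(base)
    b[2] = act([p15])
    b[3] = act([sparse[0]]) - act([sparse[-1]]) if sparse else np.nan
    b[4] = act([sparse[0]]) - b[2] if sparse else np.nan
    b[5] = act(dense) - b[2] if dense else np.nan
    b[6] = _mean_over(summaries, "omr", red)
    b[7] = _mean_over(summaries, "omr", green)
    b[8] = _mean_over(summaries, "omr", blue)
    b[9] = _mean_over(summaries, "omr", fast)
    b[10] = float(np.nanmean([b[6], b[7], b[8]])) if not all(
        math.isnan(x) for x in (b[6], b[7], b[8])
    ) else np.nan
    b[11] = _mean_over(summaries, "scoot", base)
    b[12] = _mean_over(summaries, "scoot", lines)
    b[13] = _mean_over(summaries, "burst", base)
    b[14] = _mean_over(summaries, "burst", lines)
    b[15] = _mean_over(summaries, "edge", base)
    b[16] = _mean_over(summaries, "edge", lines)
    b[17] = _mean_over(summaries, "clockwise", base)
    b[18] = _mean_over(summaries, "clockwise", lines)
    b[19] = _mean_over(summaries, "up", red)
    b[20] = _mean_over(summaries, "up", green)
    b[21] = _mean_over(summaries, "up", blue)
    b[22] = _mean_over(summaries, "up", fast)
    b[23] = float(np.nanmean([b[19], b[20], b[21]])) if not all(
        math.isnan(x) for x in (b[19], b[20], b[21])
    ) else np.nan
    b[24] = _mean_over(summaries, "turn", base)
    b[25] = _mean_over(summaries, "abs_turn", base)

    return pd.Series(
        [b[i] for i in range(1, 26)], index=list(BEHAVIOR_NAMES), dtype=float
    )


@dataclass
class QCReport:
    """Per-larva inclusion decisions with reasons for exclusion."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["well_id", "kept", "reason"])
    )

    @property
    def n_excluded(self) -> int:
        return int((~self.records["kept"]).sum())


def qc_filter(
    tracks: Iterable["PoseTrack"],
    geom: PlateGeometry,
    qc: QCConfig | None = None,
    thr: MovementThresholds | None = None,
) -> tuple[list["PoseTrack"], QCReport]:
    """Drop larvae that moved in fewer than ``min_move_fraction`` of
    their valid frame transitions over the whole session."""
    qc = qc or QCConfig()
    thr = thr or MovementThresholds()
    kept: list["PoseTrack"] = []
    recs = []
    for tr in tracks:
        kin = derive_kinematics(tr, geom, qc, thr)
        cls = kin.movement_class
        defined = cls >= 0
        n_def = int(defined.sum())
        moved = int(((cls == SCOOT) | (cls == BURST)).sum())
        if n_def == 0:
            recs.append({"well_id": tr.well_id, "kept": False, "reason": "no_valid_frames"})
        elif moved / n_def < qc.min_move_fraction:
            recs.append({"well_id": tr.well_id, "kept": False, "reason": "min_move_fraction"})
        else:
            recs.append({"well_id": tr.well_id, "kept": True, "reason": ""})
            kept.append(tr)
    return kept, QCReport(pd.DataFrame(recs))


def behavior_table(
    tracks: Iterable["PoseTrack"],
    schedule: StimulusSchedule,
    geom: PlateGeometry,
    qc: QCConfig | None = None,
    thr: MovementThresholds | None = None,
    apply_qc: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Per-larva behavior table: one row per surviving well, the 25
    canonical behaviors as columns."""
    qc = qc or QCConfig()
    thr = thr or MovementThresholds()
    tracks = list(tracks)
    if apply_qc:
        tracks, report = qc_filter(tracks, geom, qc, thr)
    else:
        report = QCReport(
            pd.DataFrame(
                {"well_id": [t.well_id for t in tracks],
                 "kept": True, "reason": ""}
            )
        )
    rows = {}
    for tr in tracks:
        kin = derive_kinematics(tr, geom, qc, thr)
        summ = period_summaries(kin, schedule, qc, thr)
        rows[tr.well_id] = behavior_vector(summ, schedule)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=list(BEHAVIOR_NAMES))
    table.index.name = "well_id"
    return table, report
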