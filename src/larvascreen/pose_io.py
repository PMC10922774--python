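"""Readers and writers for pose tracks, treatment maps and profile tables.

Two CSV dialects carry pose tracks:

``long``
    One row per (well, frame, bodypart) with columns
    ``well,frame,time_s,bodypart,x,y,likelihood``; coordinates are mm in
    a y-up frame.

``dlc_wide``
    The DeepLabCut-style wide layout: three header rows (scorer /
    bodyparts / coords) above a frame-index column and one
    ``x, y, likelihood`` column triple per (well, bodypart).  The scorer
    row carries the well ID so several wells can share a file.  Native
    coordinates are image-convention y-down and are flipped to y-up on
    read; frame times are reconstructed as frame_index x 6 s.

All files are UTF-8, comma-separated, "." decimal.  Coordinates are
printed at fixed six-decimal precision, which round-trips bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import BEHAVIOR_NAMES
from .profiling import ProfileMatrix

BODYPARTS = ("right_eye", "left_eye", "yolk")
COORD_FMT = "%.6f"
DEFAULT_FRAME_INTERVAL_S = 6.0


class FormatError(ValueError):
    pass


class DuplicateRecordError(ValueError):
    pass


@dataclass
class PoseTrack:
    """Pose time series for one larva in one well.

    ``coords`` has shape (n_frames, 3, 2) ordered (right_eye, left_eye,
    yolk), mm in a y-up frame; ``likelihood`` has shape (n_frames, 3).
    """

    well_id: str
    time_s: np.ndarray
    coords: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = len(self.time_s)
        if self.coords.shape != (n, 3, 2) or self.likelihood.shape != (n, 3):
            raise FormatError(
                f"track {self.well_id}: inconsistent array shapes"
            )
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise FormatError(
                    f"track {self.well_id}: frame times must increase with constant spacing"
                )
        lik = self.likelihood[np.isfinite(self.likelihood)]
        if np.any(lik < 0) or np.any(lik > 1):
            raise FormatError(
                f"track {self.well_id}: likelihoods must lie in [0, 1]"
            )
        # non-finite coordinates become likelihood-0 points
        bad = ~np.all(np.isfinite(self.coords), axis=2)
        if bad.any():
            self.likelihood = self.likelihood.copy()
            self.likelihood[bad] = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


# ---------------------------------------------------------------------------
# pose-track I/O
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["well", "frame", "time_s", "bodypart", "x", "y", "likelihood"]


def _tracks_to_long(tracks: list[PoseTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames):
            for b, bp in enumerate(BODYPARTS):
                rows.append(
                    (tr.well_id, i, tr.time_s[i], bp,
                     tr.coords[i, b, 0], tr.coords[i, b, 1],
                     tr.likelihood[i, b])
                )
    return pd.DataFrame(rows, columns=_LONG_COLUMNS)


def _read_long(path) -> list[PoseTrack]:
    df = pd.read_csv(path)
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"long dialect: missing columns {missing}")
    if df.duplicated(subset=["well", "frame", "bodypart"]).any():
        dup = df[df.duplicated(subset=["well", "frame", "bodypart"])].iloc[0]
        raise DuplicateRecordError(
            f"duplicate record (well={dup['well']}, frame={dup['frame']}, "
            f"bodypart={dup['bodypart']})"
        )
    unknown = set(df["bodypart"]) - set(BODYPARTS)
    if unknown:
        raise FormatError(f"unknown body parts {sorted(unknown)}")
    tracks = []
    for well, g in df.groupby("well", sort=True):
        frames = np.sort(g["frame"].unique())
        n = len(frames)
        coords = np.full((n, 3, 2), np.nan)
        lik = np.zeros((n, 3))
        t = np.empty(n)
        fidx = {f: i for i, f in enumerate(frames)}
        for _, r in g.iterrows():
            i = fidx[r["frame"]]
            b = BODYPARTS.index(r["bodypart"])
            coords[i, b] = (r["x"], r["y"])
            lik[i, b] = r["likelihood"]
            t[i] = r["time_s"]
        tracks.append(PoseTrack(str(well), t, coords, lik))
    return tracks


def _write_long(tracks: list[PoseTrack], path) -> None:
    df = _tracks_to_long(tracks)
    df.to_csv(path, index=False, float_format=COORD_FMT)


_DLC_EMPTY = "scorer\nbodyparts\ncoords\n"


def _write_dlc_wide(tracks: list[PoseTrack], path) -> None:
    if not tracks:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_DLC_EMPTY)
        return
    # y flipped back to the image (y-down) convention on write
    cols = {}
    n = tracks[0].n_frames
    for tr in tracks:
        if tr.n_frames != n:
            raise FormatError("dlc_wide requires equal-length tracks per file")
        for b, bp in enumerate(BODYPARTS):
            cols[(tr.well_id, bp, "x")] = tr.coords[:, b, 0]
            cols[(tr.well_id, bp, "y")] = -tr.coords[:, b, 1]
            cols[(tr.well_id, bp, "likelihood")] = tr.likelihood[:, b]
    df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="coords"))
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["scorer", "bodyparts", "coords"]
    )
    df.to_csv(path, float_format=COORD_FMT)


def _read_dlc_wide(path, frame_interval_s: float) -> list[PoseTrack]:
    with open(path, encoding="utf-8") as fh:
        if fh.read() == _DLC_EMPTY:
            return []
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as e:
        raise FormatError(f"dlc_wide: cannot parse three header rows: {e}") from e
    if len(df.columns.levels) != 3:
        raise FormatError("dlc_wide: expected scorer/bodyparts/coords header rows")
    tracks = []
    wells = list(dict.fromkeys(df.columns.get_level_values(0)))
    n = len(df)
    t = np.asarray(df.index, dtype=float) * frame_interval_s
    for well in wells:
        sub = df[well]
        coords = np.full((n, 3, 2), np.nan)
        lik = np.zeros((n, 3))
        for b, bp in enumerate(BODYPARTS):
            if bp not in sub.columns.get_level_values(0):
                raise FormatError(f"dlc_wide: well {well} lacks bodypart {bp!r}")
            block = sub[bp]
            for want in ("x", "y", "likelihood"):
                if want not in block.columns:
                    raise FormatError(
                        f"dlc_wide: well {well}/{bp} lacks coordinate column {want!r}"
                    )
            coords[:, b, 0] = block["x"].to_numpy(dtype=float)
            coords[:, b, 1] = -block["y"].to_numpy(dtype=float)  # flip to y-up
            lik[:, b] = block["likelihood"].to_numpy(dtype=float)
        tracks.append(PoseTrack(str(well), t, coords, lik))
    return tracks


def read_pose_tracks(
    path, dialect: str = "long",
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> list[PoseTrack]:
    """Read pose tracks from CSV in the ``long`` or ``dlc_wide`` dialect."""
    if dialect == "long":
        return _read_long(path)
    if dialect == "dlc_wide":
        return _read_dlc_wide(path, frame_interval_s)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_pose_tracks(tracks, path, dialect: str = "long") -> None:
    """Write pose tracks to CSV; ``read_pose_tracks`` reproduces the
    values bit-for-bit at the fixed printed precision."""
    tracks = list(tracks)
    if dialect == "long":
        _write_long(tracks, path)
    elif dialect == "dlc_wide":
        _write_dlc_wide(tracks, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# treatment map
# ---------------------------------------------------------------------------

ROLES = ("treatment", "dmso_control", "water_control")


@dataclass
class TreatmentMap:
    """Well-to-treatment assignment.

    ``entries`` is indexed by well ID with columns ``compound_id, role,
    concentration_uM, exposure_h`` and optionally ``batch``.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"compound_id", "role"}
        missing = need - set(self.entries.columns)
        if missing:
            raise FormatError(f"treatment map lacks columns {sorted(missing)}")
        if self.entries.index.duplicated().any():
            raise DuplicateRecordError("duplicate well in treatment map")
        bad = set(self.entries["role"]) - set(ROLES)
        if bad:
            raise FormatError(f"unknown roles {sorted(bad)}")
        if "concentration_uM" not in self.entries.columns:
            self.entries["concentration_uM"] = 10.0
        if "exposure_h" not in self.entries.columns:
            self.entries["exposure_h"] = 6.0

    def role_wells(self, role: str) -> list[str]:
        return list(self.entries.index[self.entries["role"] == role])

    def compound_of(self, well: str) -> str:
        return self.entries.loc[well, "compound_id"]

    def to_csv(self, path) -> None:
        out = self.entries.copy()
        out.index.name = "well"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TreatmentMap":
        df = pd.read_csv(path, index_col="well", dtype={"well": str})
        return cls(df)


# ---------------------------------------------------------------------------
# profile table (SD1-style)
# ---------------------------------------------------------------------------

def read_profile_table(path) -> ProfileMatrix:
    """Read a compounds x 25 behavioral-profile CSV.

    The file must contain a compound-ID column (named ``compound_id``,
    or the first unnamed column) and exactly the 25 canonical behavior
    columns, matched by name in any order.  Empty cells stay missing.
    """
    df = pd.read_csv(path)
    id_col = "compound_id" if "compound_id" in df.columns else df.columns[0]
    df = df.set_index(id_col)
    have = set(df.columns)
    want = set(BEHAVIOR_NAMES)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise FormatError(
            "profile table schema mismatch; expected exactly the 25 canonical "
            f"behavior columns. Missing: {missing}. Unexpected: {extra}."
        )
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateRecordError(f"duplicate compound IDs: {dups}")
    df = df[list(BEHAVIOR_NAMES)].astype(float)
    df.index = df.index.astype(str)
    return ProfileMatrix(values=df)
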