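"""Synthetic screen generator.

Larval trajectories are simulated as a stimulus-modulated correlated
random walk inside the well: per 6-s transition the larva moves with a
probability modulated by acoustic-stimulus terms (startle to sparse
20-s-interval stimuli with per-stimulus habituation, an excitability
baseline shift during any acoustic period), draws a scoot- or
burst-scale displacement along its heading, and re-orients by mixing its
previous heading with attractors toward the moving-line direction
(optomotor gain) and "up" (orientation gain), plus angular noise.
Thigmotaxis biases steps outward; the well wall reflects.  Body points
(two eyes 0.3 mm apart, yolk 0.5 mm behind) are placed from position and
heading, with likelihoods in [0.9, 1] and an optional corruption rate
pushing a fraction below the QC threshold.

Drug effects are *archetypes*: additive offsets on the walk parameters.
The CsA-like archetype raises activity, scoot probability and
excitability while lowering startle, habituation, optomotor and upward
orientation gains.  The generator makes no claim of biological fidelity;
it exposes every one of the 25 measured behaviors with known ground
truth so the analysis pipeline can be validated end to end.

A fast profile-level generator (`simulate_profile_matrix`) skips the
trajectories and draws compound profiles directly around per-archetype
mean vectors with independent noise, planting cluster structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .assay import (
    KIND_ACOUSTIC,
    KIND_LINES,
    PERIOD_S,
    PlateGeometry,
    StimulusSchedule,
)
from .metrics import BEHAVIOR_NAMES
from .pose_io import PoseTrack, TreatmentMap
from .profiling import ProfileMatrix

EYE_SEPARATION_MM = 0.3
YOLK_OFFSET_MM = 0.5


@dataclass
class LarvaParams:
    """Parameters of the correlated random walk, per 6-s transition."""

    p_move: float = 0.30
    scoot_mm: float = 0.5
    burst_mm: float = 2.0
    p_burst_given_move: float = 0.30
    heading_persistence: float = 0.5
    omr_gain: float = 0.40
    up_gain: float = 0.25
    thigmotaxis: float = 0.40
    startle_gain: float = 0.25
    habituation_rate: float = 0.005
    excitability_gain: float = 0.10
    heading_noise_deg: float = 60.0
    corruption_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.scoot_mm < self.burst_mm:
            raise ValueError("need 0 < scoot_mm < burst_mm")
        for name in ("p_move", "p_burst_given_move", "heading_persistence",
                     "omr_gain", "up_gain", "thigmotaxis", "habituation_rate",
                     "corruption_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def with_offsets(self, offsets: dict[str, float]) -> "LarvaParams":
        """Apply additive offsets, clipping probabilities and gains back
        into range."""
        unit = {"p_move", "p_burst_given_move", "heading_persistence",
                "omr_gain", "up_gain", "thigmotaxis", "habituation_rate",
                "corruption_rate"}
        kw = {}
        for f in fields(self):
            v = getattr(self, f.name) + offsets.get(f.name, 0.0)
            if f.name in unit:
                v = min(max(v, 0.0), 1.0)
            elif f.name in ("scoot_mm", "burst_mm", "heading_noise_deg",
                            "startle_gain", "excitability_gain"):
                v = max(v, 0.0)
            kw[f.name] = v
        return LarvaParams(**kw)


@dataclass(frozen=True)
class EffectArchetype:
    """A named drug-effect archetype: additive offsets on LarvaParams."""

    name: str
    offsets: dict[str, float] = field(default_factory=dict)

    def apply(self, base: LarvaParams) -> LarvaParams:
        return base.with_offsets(self.offsets)


ARCHETYPES: dict[str, EffectArchetype] = {
    "inert": EffectArchetype("inert", {}),
    "csa_like": EffectArchetype("csa_like", {
        "p_move": +0.15,
        "p_burst_given_move": -0.15,
        "startle_gain": -0.15,
        "habituation_rate": -0.004,
        "excitability_gain": +0.08,
        "omr_gain": -0.30,
        "up_gain": -0.17,
        "heading_noise_deg": +40.0,
    }),
    "sedative": EffectArchetype("sedative", {
        "p_move": -0.20,
        "startle_gain": -0.10,
        "excitability_gain": -0.05,
        "omr_gain": -0.15,
        "p_burst_given_move": -0.10,
    }),
    "stimulant": EffectArchetype("stimulant", {
        "p_move": +0.25,
        "p_burst_given_move": +0.20,
        "startle_gain": +0.10,
        "excitability_gain": +0.05,
        "omr_gain": +0.10,
        "thigmotaxis": +0.20,
    }),
}

#: Per-archetype mean profile vectors (difference vs DMSO, percentage
#: points; degrees for the two turn behaviors), for the fast
#: profile-level generator.  The CsA-like vector follows the reference
#: signature: activity, excitability and scoot up; habituation, startle,
#: optomotor and upward orientation down.
ARCHETYPE_PROFILE_MEANS: dict[str, np.ndarray] = {
    "inert": np.zeros(25),
    "csa_like": np.array([
        15, 12, -8, -10, 8, -15, -15, -15, -12, -15,
        10, 10, 2, 2, 4, 4, 0, 0, -12, -12,
        -12, -10, -12, 0, 3,
    ], dtype=float),
    "sedative": np.array([
        -20, -15, -6, -8, -5, -10, -10, -10, -8, -10,
        -8, -8, -6, -6, -5, -5, 0, 0, -6, -6,
        -6, -5, -6, 0, -5,
    ], dtype=float),
    "stimulant": np.array([
        25, 20, 5, 10, 6, 5, 5, 5, 4, 5,
        6, 6, 10, 10, 8, 8, 0, 0, 4, 4,
        4, 3, 4, 0, 6,
    ], dtype=float),
}


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def stimuli_before(schedule: StimulusSchedule, period) -> int:
    """Acoustic stimuli delivered before ``period`` starts (each earlier
    acoustic period contributes 600 s / interstimulus interval)."""
    n = 0
    for p in schedule.periods:
        if p.index >= period.index:
            break
        if p.kind == KIND_ACOUSTIC and p.acoustic_interval_s:
            n += int(PERIOD_S // p.acoustic_interval_s)
    return n


def simulate_trajectory(
    params: LarvaParams,
    schedule: StimulusSchedule,
    geom: PlateGeometry,
    well: str,
    seed: int | np.random.Generator = 0,
) -> PoseTrack:
    """Simulate one larva's pose track for a full session.

    Deterministic given the seed (or a caller-owned Generator); all
    randomness flows from that single stream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_frames
    dt = schedule.frame_interval_s
    cx, cy = geom.center(well)
    R = geom.well_radius_mm

    # per-transition period attributes, precomputed.  Movement is
    # attributed to the transition's first frame (matching the metrics),
    # while the heading attractor follows the stimulus of the frame the
    # heading is recorded at (the destination frame).
    p_move = np.empty(n - 1)
    line_dir = np.full(n - 1, np.nan)
    for i in range(n - 1):
        per = schedule.period_of(i * dt)
        if per.kind == KIND_ACOUSTIC:
            p = params.p_move + params.excitability_gain
            if per.acoustic_interval_s == 20.0:
                n_prior = stimuli_before(schedule, per)
                p += params.startle_gain * (1.0 - params.habituation_rate) ** n_prior
        else:
            p = params.p_move
        p_move[i] = min(max(p, 0.0), 1.0)
        dest = schedule.period_of((i + 1) * dt)
        if dest.kind == KIND_LINES:
            line_dir[i] = math.radians(dest.motion_direction_deg)

    # pre-drawn randomness
    u_move = rng.random(n - 1)
    u_burst = rng.random(n - 1)
    disp_jit = rng.uniform(0.7, 1.3, n - 1)
    ang_noise = rng.normal(0.0, 1.0, n - 1)
    lik = rng.uniform(0.9, 1.0, (n, 3))
    corrupt = rng.random((n, 3)) < params.corruption_rate
    lik[corrupt] = rng.uniform(0.0, 0.5, int(corrupt.sum()))

    # initial state
    r0 = 0.5 * R * math.sqrt(rng.random())
    a0 = rng.uniform(0.0, 2 * math.pi)
    x, y = cx + r0 * math.cos(a0), cy + r0 * math.sin(a0)
    theta = rng.uniform(0.0, 2 * math.pi)

    up = math.pi / 2
    noise_sd = math.radians(params.heading_noise_deg) * (1.0 - params.heading_persistence)
    pos = np.empty((n, 2))
    head = np.empty(n)
    pos[0] = (x, y)
    head[0] = theta

    for i in range(n - 1):
        # heading re-orients every transition: attractor mix plus noise
        # (larvae can turn in place without translating)
        w_o = params.omr_gain if not math.isnan(line_dir[i]) else 0.0
        w_u = params.up_gain
        a = min(w_o + w_u, 1.0)
        if a > 0.0:
            tx = w_o * math.cos(line_dir[i]) if w_o else 0.0
            ty = w_o * math.sin(line_dir[i]) if w_o else 0.0
            tx += w_u * math.cos(up)
            ty += w_u * math.sin(up)
            tnorm = math.hypot(tx, ty)
            vx = (1.0 - a) * math.cos(theta) + a * tx / tnorm
            vy = (1.0 - a) * math.sin(theta) + a * ty / tnorm
            theta = math.atan2(vy, vx)
        if a < 1.0:
            theta += ang_noise[i] * noise_sd
        if u_move[i] < p_move[i]:
            burst = u_burst[i] < params.p_burst_given_move
            d = (params.burst_mm if burst else params.scoot_mm) * disp_jit[i]
            sx = d * math.cos(theta)
            sy = d * math.sin(theta)
            # thigmotaxis: outward radial bias
            rx, ry = x - cx, y - cy
            rr = math.hypot(rx, ry)
            if rr > 1e-9 and params.thigmotaxis > 0:
                sx += params.thigmotaxis * 0.3 * d * rx / rr
                sy += params.thigmotaxis * 0.3 * d * ry / rr
            # wall handling: a step that would exit bounces by reversing
            # its radial component (preserving step length); residual
            # exits fold back across the rim.  The intended heading is
            # not overwritten by the bounce.
            if math.hypot(x + sx - cx, y + sy - cy) > R and rr > 1e-9:
                s_rad = (sx * rx + sy * ry) / rr
                if s_rad > 0.0:
                    sx -= 2.0 * s_rad * rx / rr
                    sy -= 2.0 * s_rad * ry / rr
            x += sx
            y += sy
            rx, ry = x - cx, y - cy
            rr = math.hypot(rx, ry)
            if rr > R:
                rnew = max(2 * R - rr, 0.0)
                x = cx + rnew * rx / rr
                y = cy + rnew * ry / rr
        pos[i + 1] = (x, y)
        head[i + 1] = theta

    # place body points from position + heading
    hx, hy = np.cos(head), np.sin(head)
    px, py = hy, -hx  # right-hand perpendicular (y-up frame)
    coords = np.empty((n, 3, 2))
    coords[:, 0, 0] = pos[:, 0] + 0.5 * EYE_SEPARATION_MM * px
    coords[:, 0, 1] = pos[:, 1] + 0.5 * EYE_SEPARATION_MM * py
    coords[:, 1, 0] = pos[:, 0] - 0.5 * EYE_SEPARATION_MM * px
    coords[:, 1, 1] = pos[:, 1] - 0.5 * EYE_SEPARATION_MM * py
    coords[:, 2, 0] = pos[:, 0] - YOLK_OFFSET_MM * hx
    coords[:, 2, 1] = pos[:, 1] - YOLK_OFFSET_MM * hy

    t = np.arange(n) * dt
    return PoseTrack(well_id=well, time_s=t, coords=coords, likelihood=lik)


# ---------------------------------------------------------------------------
# screen-level simulation
# ---------------------------------------------------------------------------

_ROWS = "ABCDEFGH"


def plate_style_ids(n: int, start_plate: int = 1) -> list[str]:
    """Compound IDs in the screen's plate-well style: M1A1..M1H12, M2A1..."""
    out = []
    for i in range(n):
        plate = start_plate + i // 96
        pos = i % 96
        out.append(f"M{plate}{_ROWS[pos // 12]}{pos % 12 + 1}")
    return out


@dataclass
class ScreenDesign:
    """Layout of a simulated screen.

    ``archetypes`` assigns an archetype name to every compound (by
    index); DMSO control larvae are drawn from the unmodified baseline
    parameters.
    """

    n_compounds: int
    n_larvae_per_compound: int = 48
    archetypes: list[str] = field(default_factory=list)
    n_dmso_controls: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_larvae_per_compound < 1:
            raise ValueError("counts must be positive")
        if not self.archetypes:
            self.archetypes = ["inert"] * self.n_compounds
        if len(self.archetypes) != self.n_compounds:
            raise ValueError("archetype assignment must cover all compounds")
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")

    @property
    def compound_ids(self) -> list[str]:
        return plate_style_ids(self.n_compounds)

    @property
    def n_treated_larvae(self) -> int:
        return self.n_compounds * self.n_larvae_per_compound

    @property
    def n_total_larvae(self) -> int:
        return self.n_treated_larvae + self.n_dmso_controls


def simulate_screen(
    design: ScreenDesign,
    schedule: StimulusSchedule,
    geom: PlateGeometry,
    base_params: LarvaParams | None = None,
) -> tuple[list[PoseTrack], TreatmentMap, pd.Series]:
    """Simulate pose tracks for a whole screen.

    One larva per (virtual) well; wells are named ``p<plate>_<well>``.
    Returns the tracks, the treatment map and the per-compound archetype
    truth labels.
    """
    base = base_params or LarvaParams()
    rng = np.random.default_rng(design.seed)
    all_wells = [f"{r}{c}" for r in _ROWS for c in range(1, 13)]

    jobs: list[tuple[str, str, LarvaParams]] = []  # (well, compound/role, params)
    cids = design.compound_ids
    for cid, arch in zip(cids, design.archetypes):
        p = ARCHETYPES[arch].apply(base)
        for _ in range(design.n_larvae_per_compound):
            jobs.append((cid, "treatment", p))
    for _ in range(design.n_dmso_controls):
        jobs.append(("DMSO", "dmso_control", base))

    tracks: list[PoseTrack] = []
    entries = []
    for j, (cid, role, p) in enumerate(jobs):
        plate = j // 96 + 1
        well = all_wells[j % 96]
        uwell = f"p{plate}_{well}"
        tracks.append(simulate_trajectory(p, schedule, geom, well=well, seed=rng))
        # the simulated track keeps the geometric well name; re-label with
        # the unique screen-wide well ID
        tracks[-1].well_id = uwell
        entries.append({"well": uwell, "compound_id": cid, "role": role,
                        "concentration_uM": 10.0, "exposure_h": 6.0})
    tmap = TreatmentMap(pd.DataFrame(entries).set_index("well"))
    truth = pd.Series(dict(zip(cids, design.archetypes)), name="archetype")
    return tracks, tmap, truth


def simulate_profile_matrix(
    n_compounds: int = 876,
    n_reference_like: int = 59,
    within_sd: float = 3.0,
    seed: int = 0,
    archetype_means: dict[str, np.ndarray] | None = None,
    rest_proportions: dict[str, float] | None = None,
) -> tuple[ProfileMatrix, pd.Series, str]:
    """Draw a compounds x 25 profile matrix with planted cluster structure.

    ``n_reference_like`` rows (including the designated reference
    compound) are drawn around the CsA-like archetype mean; the rest are
    split among the other archetypes.  Rows are archetype mean plus
    independent Gaussian noise (SD ``within_sd`` per behavior).  Returns
    the matrix, per-compound archetype truth and the reference ID
    ("M1G11" whenever the library is large enough to contain it).
    """
    if n_reference_like < 1 or n_reference_like > n_compounds:
        raise ValueError("n_reference_like out of range")
    means = archetype_means or ARCHETYPE_PROFILE_MEANS
    if len(means) < 2:
        raise ValueError("need at least 2 archetypes")
    rest_proportions = rest_proportions or {
        "inert": 0.5, "sedative": 0.25, "stimulant": 0.25
    }
    rng = np.random.default_rng(seed)
    ids = plate_style_ids(n_compounds)
    reference_id = "M1G11" if "M1G11" in ids else ids[0]

    # archetype assignment: reference + (n_reference_like - 1) random others
    labels = pd.Series("", index=ids, dtype=object)
    others = [c for c in ids if c != reference_id]
    csa_extra = list(rng.choice(others, size=n_reference_like - 1, replace=False))
    labels[reference_id] = "csa_like"
    labels[csa_extra] = "csa_like"
    rest = [c for c in ids if labels[c] == ""]
    names = [k for k in rest_proportions if k in means]
    prop = np.array([rest_proportions[k] for k in names], dtype=float)
    prop = prop / prop.sum()
    counts = np.floor(prop * len(rest)).astype(int)
    counts[0] += len(rest) - counts.sum()
    pool = [n for n, c in zip(names, counts) for _ in range(c)]
    pool = list(rng.permutation(pool))
    labels[rest] = pool

    rows = np.empty((n_compounds, 25))
    for i, cid in enumerate(ids):
        rows[i] = means[labels[cid]] + rng.normal(0.0, within_sd, 25)
    values = pd.DataFrame(rows, index=ids, columns=list(BEHAVIOR_NAMES))
    pm = ProfileMatrix(values=values)
    return pm, labels.rename("archetype"), reference_id
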