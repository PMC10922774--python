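import numpy as np
import pandas as pd
import pytest

from larvascreen import (
    LarvaParams,
    QCConfig,
    behavior_table,
    behavior_vector,
    derive_kinematics,
    period_summaries,
    qc_filter,
    simulate_trajectory,
)
from larvascreen.metrics import (
    BEHAVIOR_NAMES,
    BURST,
    REST,
    SCOOT,
    InsufficientDataError,
    MovementThresholds,
)

B = list(BEHAVIOR_NAMES)
PCT_BEHAVIORS = [n for n in B if n not in (B[23], B[24], B[2], B[3], B[4])]


class TestDeriveKinematics:
    def test_axis_aligned_heading(self, make_track):
        kin = derive_kinematics(make_track([(0, 0), (0, 0)], [90.0, 90.0]), geom=_g())
        np.testing.assert_allclose(kin.heading_deg, [90.0, 90.0])

    @pytest.mark.parametrize("step,expected", [
        (0.0, REST), (0.1, REST), (0.5, SCOOT), (0.99, SCOOT), (1.0, BURST), (3.0, BURST),
    ])
    def test_movement_classes(self, make_track, step, expected):
        kin = derive_kinematics(
            make_track([(0, 0), (step, 0)], [0.0, 0.0]), geom=_g()
        )
        assert kin.displacement_mm[0] == pytest.approx(step)
        assert kin.movement_class[0] == expected

    def test_low_likelihood_frame_invalidated(self, make_track):
        lik = np.ones((3, 3))
        lik[1, 2] = 0.4  # yolk below threshold on frame 1
        tr = make_track([(0, 0), (0.5, 0), (1.0, 0)], [0.0] * 3, likelihood=lik)
        kin = derive_kinematics(tr, geom=_g())
        assert not kin.valid[1]
        assert np.isnan(kin.heading_deg[1])
        assert kin.movement_class[0] == -1 and kin.movement_class[1] == -1

    def test_degrading_frames_leaves_other_frames_unchanged(self, schedule, geom):
        tr = simulate_trajectory(LarvaParams(corruption_rate=0.0), schedule, geom, "C4", seed=7)
        kin0 = derive_kinematics(tr, geom)
        lik = tr.likelihood.copy()
        drop = [100, 500, 900]
        lik[drop, :] = 0.1
        tr2 = type(tr)(tr.well_id, tr.time_s, tr.coords, lik)
        kin1 = derive_kinematics(tr2, geom)
        keep = np.ones(kin0.n_frames, bool)
        keep[drop] = False
        np.testing.assert_array_equal(kin0.heading_deg[keep], kin1.heading_deg[keep])
        np.testing.assert_array_equal(kin0.r_frac[keep], kin1.r_frac[keep])
        tkeep = keep[:-1] & keep[1:]
        np.testing.assert_array_equal(
            kin0.displacement_mm[tkeep], kin1.displacement_mm[tkeep]
        )

    def test_single_frame_track_rejected(self, make_track):
        with pytest.raises(InsufficientDataError):
            derive_kinematics(make_track([(0, 0)], [0.0]), geom=_g())


def _g():
    from larvascreen import PlateGeometry

    return PlateGeometry()


class TestPeriodSummaries:
    def test_motionless_larva_zero_activity(self, make_track, schedule, geom):
        n = schedule.n_frames
        tr = make_track([(0, 0)] * n, [0.0] * n)
        summ = period_summaries(derive_kinematics(tr, geom), schedule)
        assert (summ["activity"] == 0).all()
        assert (summ["scoot"] == 0).all()

    def test_heading_90_during_lines(self, full_session_track, schedule, geom):
        summ = period_summaries(derive_kinematics(full_session_track(), geom), schedule)
        # motion direction in P7 is 0 deg: heading 90 is outside the +/-45 cone
        assert summ.loc[7, "omr"] == 0.0
        assert summ.loc[7, "up"] == 100.0

    def test_clockwise_complementarity(self, schedule, geom):
        tr = simulate_trajectory(LarvaParams(corruption_rate=0.0), schedule, geom, "B3", seed=3)
        kin = derive_kinematics(tr, geom)
        cw = int((kin.cw_sign == -1).sum())
        ccw = int((kin.cw_sign == 1).sum())
        defined = int(np.isfinite(kin.cw_sign).sum()) - int((kin.cw_sign == 0).sum())
        assert cw + ccw == defined

    def test_sparse_period_reported_missing(self, make_track, schedule, geom):
        n = schedule.n_frames
        lik = np.ones((n, 3))
        lik[:100, :] = 0.2  # all of period 1 invalid
        tr = make_track([(0, 0)] * n, [0.0] * n, likelihood=lik)
        summ = period_summaries(derive_kinematics(tr, geom), schedule)
        assert np.isnan(summ.loc[1, "activity"])
        assert summ.loc[2, "activity"] == 0.0


class TestBehaviorVector:
    def _summaries(self, schedule, overrides=()):
        df = pd.DataFrame(
            0.0, index=range(1, 19),
            columns=["activity", "scoot", "burst", "edge", "clockwise",
                     "omr", "up", "turn", "abs_turn", "valid_frac"],
        )
        df.index.name = "period"
        df["valid_frac"] = 1.0
        df.loc[1:6, "omr"] = np.nan
        df.loc[15:18, "omr"] = np.nan
        for (col, period), val in dict(overrides).items():
            df.loc[period, col] = val
        return df

    def test_combined_omr_is_mean_of_colors(self, schedule):
        s = self._summaries(
            schedule,
            {("omr", 7): 80.0, ("omr", 8): 80.0, ("omr", 9): 40.0,
             ("omr", 10): 40.0, ("omr", 11): 40.0, ("omr", 12): 40.0},
        )
        v = behavior_vector(s, schedule)
        assert v[B[5]] == pytest.approx(80.0)
        assert v[B[9]] == pytest.approx((80 + 40 + 40) / 3)

    def test_uniform_activity_zeroes_contrasts(self, schedule):
        s = self._summaries(schedule)
        s["activity"] = 100.0
        v = behavior_vector(s, schedule)
        assert v[B[0]] == 100.0
        assert v[B[2]] == 0.0  # habituation
        assert v[B[3]] == 0.0  # startle

    def test_canonical_order(self, schedule):
        v = behavior_vector(self._summaries(schedule), schedule)
        assert list(v.index) == B

    def test_all_missing_component_stays_missing(self, schedule):
        s = self._summaries(schedule)
        s.loc[[7, 8], "omr"] = np.nan
        v = behavior_vector(s, schedule)
        assert np.isnan(v[B[5]])
        # combined OMR falls back to the non-missing colors
        assert v[B[9]] == pytest.approx(0.0)


class TestInvariants:
    def _vector(self, tr, schedule, geom):
        return behavior_vector(
            period_summaries(derive_kinematics(tr, geom), schedule), schedule
        )

    def test_percent_behaviors_in_range_and_abs_turn_dominates(self, schedule, geom):
        for seed in range(3):
            tr = simulate_trajectory(LarvaParams(), schedule, geom, "D6", seed=seed)
            v = self._vector(tr, schedule, geom)
            for name in (B[0], B[1], B[10], B[11], B[14], B[16], B[18], B[22]):
                assert 0.0 <= v[name] <= 100.0
            assert v[B[24]] >= abs(v[B[23]])

    def test_mirror_symmetry(self, schedule, geom):
        tr = simulate_trajectory(
            LarvaParams(corruption_rate=0.0), schedule, geom, "E5", seed=11
        )
        v = self._vector(tr, schedule, geom)
        cx = geom.center("E5")[0]
        mirrored = type(tr)(
            tr.well_id, tr.time_s,
            np.stack([2 * cx - tr.coords[:, :, 0], tr.coords[:, :, 1]], axis=2),
            tr.likelihood,
        )
        # mirroring swaps the eyes' chirality; swap them back so the
        # right-eye column remains the anatomical right eye
        mirrored.coords[:, [0, 1], :] = mirrored.coords[:, [1, 0], :]
        vm = self._vector(mirrored, schedule, geom)
        assert vm[B[23]] == pytest.approx(-v[B[23]], abs=1e-9)
        assert vm[B[24]] == pytest.approx(v[B[24]], abs=1e-9)
        assert vm[B[16]] == pytest.approx(100.0 - v[B[16]], abs=1e-9)
        for name in (B[0], B[10], B[12], B[14]):
            assert vm[name] == pytest.approx(v[name], abs=1e-9)

    def test_determinism(self, schedule, geom):
        tr = simulate_trajectory(LarvaParams(), schedule, geom, "A8", seed=21)
        v1 = self._vector(tr, schedule, geom)
        v2 = self._vector(tr, schedule, geom)
        pd.testing.assert_series_equal(v1, v2)


class TestQCFilter:
    def test_planted_motionless_larvae_excluded(self, schedule, geom):
        moving = [
            simulate_trajectory(LarvaParams(), schedule, geom, w, seed=i)
            for i, w in enumerate(["A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8"])
        ]
        immobile = LarvaParams(p_move=0.0, startle_gain=0.0, excitability_gain=0.0)
        frozen = [
            simulate_trajectory(immobile, schedule, geom, w, seed=50 + i)
            for i, w in enumerate(["B1", "B2"])
        ]
        kept, report = qc_filter(moving + frozen, geom)
        assert {t.well_id for t in kept} == {t.well_id for t in moving}
        excluded = report.records[~report.records["kept"]]
        assert set(excluded["well_id"]) == {"B1", "B2"}
        assert (excluded["reason"] == "min_move_fraction").all()

    def test_half_time_mover_kept(self, make_track, geom):
        n = 100
        xs = 0.3 * (np.arange(n) % 2)
        tr = make_track(np.stack([xs, np.zeros(n)], axis=1), [0.0] * n)
        kept, report = qc_filter([tr], geom)
        assert len(kept) == 1

    def test_behavior_table_shape(self, schedule, geom):
        tracks = [
            simulate_trajectory(LarvaParams(), schedule, geom, w, seed=i)
            for i, w in enumerate(["C1", "C2", "C3"])
        ]
        table, report = behavior_table(tracks, schedule, geom)
        assert table.shape == (3, 25)
        assert list(table.columns) == B
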