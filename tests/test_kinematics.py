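"""Bout segmentation and kinematic feature extraction."""

import numpy as np
import pandas as pd
import pytest

from finbody.kinematics import (
    LightSchedule,
    TrackedEpoch,
    align_accelerations,
    bout_features,
    bout_table,
    compute_speed,
    deviation_from_horizontal,
    filter_light_phase,
    interbout_features,
    segment_bouts,
)
from finbody.presets import preset
from finbody.simulate import generate_bout_table, render_epoch

from conftest import make_epoch

DT = 0.025  # native 40 Hz frame interval


def quiet_epoch(n=120, epoch_id="q"):
    t = np.arange(n) * DT
    return make_epoch(t, np.zeros(n), np.zeros(n), np.zeros(n), epoch_id)


class TestComputeSpeed:
    def test_stationary_fish_zero_speed(self):
        assert np.all(compute_speed(quiet_epoch()) == 0.0)

    def test_uniform_motion(self):
        n = 120
        t = np.arange(n) * DT
        x = 0.25 * np.arange(n)  # 0.25 mm per 25 ms frame
        ep = make_epoch(t, x, np.zeros(n), np.zeros(n))
        assert np.allclose(compute_speed(ep), 10.0)

    def test_halfsine_peak_within_frame_quantization(self):
        p = preset("1wpf")
        bouts = generate_bout_table(p, 1, seed=0)
        bouts.loc[0, "peak_speed_mms"] = 13.0
        ep = render_epoch(bouts, p)
        speed = compute_speed(ep)
        assert speed.max() <= 13.0 + 1e-9
        assert speed.max() == pytest.approx(13.0, abs=0.5)

    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            compute_speed(quiet_epoch(n=1))

    def test_rejects_nonuniform_sampling(self):
        t = np.arange(120) * DT
        t[60:] += 0.01
        with pytest.raises(ValueError, match="uniform"):
            make_epoch(t, np.zeros(120), np.zeros(120), np.zeros(120))


class TestSegmentBouts:
    def test_all_subthreshold_yields_empty(self):
        assert segment_bouts(quiet_epoch()) == []

    def test_short_epoch_excluded_with_reason(self):
        ep = quiet_epoch(n=40)  # 1 s < 2.5 s
        bouts, excl = segment_bouts(ep, return_exclusions=True)
        assert bouts == [] and excl["short_epoch"] == 1

    def test_bouts_faster_than_13hz_merge(self):
        """Two above-threshold runs with onsets 50 ms apart form one bout."""
        n = 120
        x = np.zeros(n)
        # displacements (mm) per frame: 8 mm/s, sub-threshold dip, 8 mm/s
        steps = {60: 0.2, 61: 0.1, 62: 0.2}
        for j in range(1, n):
            x[j] = x[j - 1] + steps.get(j - 1, 0.0)
        ep = make_epoch(np.arange(n) * DT, x, np.zeros(n), np.zeros(n))
        assert len(segment_bouts(ep)) == 1
        # with merging off (tiny merge interval) the runs stay separate
        assert len(segment_bouts(ep, merge_interval=1e-6)) == 2

    def test_counts_recovered_and_durations(self, noiseless_preset):
        """Ten rendered non-merging bouts: exact count, analytic durations."""
        bouts = generate_bout_table(noiseless_preset, 10, seed=11)
        ep = render_epoch(bouts, noiseless_preset)
        seg = segment_bouts(ep)
        assert len(seg) == 10
        assert np.allclose([b.duration for b in seg], bouts["duration_s"],
                           atol=0.5 / noiseless_preset.frame_rate)

    def test_merging_idempotent(self, rendered_fixture):
        """Returned bouts are already slower than the 13 Hz merge limit."""
        _, ep = rendered_fixture
        seg = segment_bouts(ep)
        onsets = np.array([b.onset_frame_time for b in seg])
        assert np.all(np.diff(onsets) >= 1.0 / 13.0)

    def test_backwards_trajectories_excluded_and_counted(self):
        p = preset("1wpf")
        tbl = pd.DataFrame({
            "peak_time_s": [1.0, 2.5], "peak_speed_mms": [13.0, 13.0],
            "duration_s": [0.09, 0.09], "trajectory_deg": [150.0, 10.0],
            "posture_deg": [0.0, 0.0], "posture_change_deg": [0.0, 0.0],
        })
        ep = render_epoch(tbl, p, pad=2.0)
        seg, excl = segment_bouts(ep, return_exclusions=True)
        assert len(seg) == 1 and excl["backwards"] == 1


class TestBoutFeatures:
    def test_vertical_motion_horizontal_posture(self):
        """Pointing horizontally while moving straight up: attack angle 90."""
        n = 120
        z = np.zeros(n)
        for j in range(1, n):
            z[j] = z[j - 1] + (0.25 if 60 <= j - 1 <= 63 else 0.0)
        ep = make_epoch(np.arange(n) * DT, np.zeros(n), z, np.zeros(n))
        [bout] = segment_bouts(ep)
        assert bout.trajectory == pytest.approx(90.0)
        assert bout.attack_angle == pytest.approx(90.0)

    def test_attack_angle_is_trajectory_minus_posture(self):
        p = preset("1wpf")
        tbl = pd.DataFrame({
            "peak_time_s": [1.0], "peak_speed_mms": [13.0], "duration_s": [0.09],
            "trajectory_deg": [10.0], "posture_deg": [20.0], "posture_change_deg": [0.0],
        })
        ep = render_epoch(tbl, p, pad=2.0)
        [bout] = segment_bouts(ep)
        assert bout.trajectory == pytest.approx(10.0, abs=1e-6)
        assert bout.posture_at_peak == pytest.approx(20.0, abs=1e-6)
        assert bout.attack_angle == pytest.approx(-10.0, abs=1e-6)

    def test_identity_exact_for_all_bouts(self, rendered_fixture):
        _, ep = rendered_fixture
        for b in segment_bouts(ep):
            assert b.attack_angle == b.trajectory - b.posture_at_peak

    def test_posture_ramp_measured_over_window(self):
        """A commanded 40 deg/s ramp spanning the window gives 2.0 deg."""
        p = preset("1wpf")
        tbl = pd.DataFrame({
            "peak_time_s": [1.0], "peak_speed_mms": [13.0], "duration_s": [0.09],
            "trajectory_deg": [5.0], "posture_deg": [3.0],
            "posture_change_deg": [2.0],  # 2 deg over the 50 ms window = 40 deg/s
        })
        ep = render_epoch(tbl, p, pad=2.0)
        [bout] = segment_bouts(ep)
        assert bout.valid_posture_change
        assert bout.posture_change == pytest.approx(2.0, abs=1e-9)

    def test_recompute_matches_segmentation(self, rendered_fixture):
        _, ep = rendered_fixture
        for b in segment_bouts(ep):
            again = bout_features(ep, b)
            assert again.peak_speed == pytest.approx(b.peak_speed)
            assert again.posture_change == pytest.approx(b.posture_change, nan_ok=True)

    def test_malformed_bout_rejected(self, rendered_fixture):
        _, ep = rendered_fixture
        [b, *_] = segment_bouts(ep)
        import dataclasses

        broken = dataclasses.replace(b, onset_time=b.onset_time - 2.0,
                                     offset_time=b.onset_time - 1.9)
        with pytest.raises(ValueError, match="malformed"):
            bout_features(ep, broken)


class TestInterboutFeatures:
    def render_pair(self, gap, sink=1.0):
        p = preset("1wpf")
        p.sink_speed = sink
        tbl = pd.DataFrame({
            "peak_time_s": [1.0, 1.0 + gap], "peak_speed_mms": [13.0, 13.0],
            "duration_s": [0.09, 0.09], "trajectory_deg": [0.0, 0.0],
            "posture_deg": [0.0, 0.0], "posture_change_deg": [0.0, 0.0],
        })
        ep = render_epoch(tbl, p, pad=2.0)
        return ep, segment_bouts(ep)

    def test_rate_from_onset_interval(self):
        ep, bouts = self.render_pair(1.0)
        tab = interbout_features(bouts, ep)
        assert len(tab) == 1
        assert tab["rate_hz"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_sinking_vertical_displacement(self):
        """1 mm/s sink over a ~0.9 s inter-bout drops the centroid ~0.9 mm."""
        ep, bouts = self.render_pair(1.0, sink=1.0)
        tab = interbout_features(bouts, ep)
        expected = -(tab["interbout_duration_s"].iloc[0]) * 1.0
        assert tab["interbout_dz_mm"].iloc[0] == pytest.approx(expected, abs=0.05)
        assert tab["interbout_dz_mm"].iloc[0] == pytest.approx(-0.9, abs=0.1)

    def test_single_bout_empty_result(self):
        p = preset("1wpf")
        tbl = generate_bout_table(p, 1, seed=0)
        ep = render_epoch(tbl, p, pad=2.0)
        bouts = segment_bouts(ep)
        assert interbout_features(bouts, ep).empty

    def test_no_pairs_across_epochs(self):
        ep1, bouts1 = self.render_pair(1.0)
        ep2 = make_epoch(ep1.time, ep1.x, ep1.z, ep1.posture, epoch_id="other")
        mixed = [bouts1[0]] + [b for b in segment_bouts(ep2)][1:]
        assert interbout_features(mixed, ep1).empty


class TestDeviationFromHorizontal:
    def test_trivial_cases(self):
        assert deviation_from_horizontal(quiet_epoch()) == 0.0
        n = 120
        p = np.resize([10.0, -10.0], n)
        ep = make_epoch(np.arange(n) * DT, np.zeros(n), np.zeros(n), p)
        assert deviation_from_horizontal(ep) == pytest.approx(10.0)

    def test_half_normal_mean(self):
        """|N(0, 15^2)| has mean 15*sqrt(2/pi) ~ 11.97."""
        rng = np.random.default_rng(0)
        n = 100_000
        post = rng.normal(0, 15, n)
        ep = make_epoch(np.arange(n) * DT, np.zeros(n), np.zeros(n), post)
        assert deviation_from_horizontal(ep) == pytest.approx(15 * np.sqrt(2 / np.pi), abs=0.15)


class TestAlignAccelerations:
    def test_constant_speed_segments_have_zero_linear_acceleration(self):
        """Away from the speed bump the (constant-sink) trace is flat zero."""
        p = preset("1wpf")
        tbl = pd.DataFrame({
            "peak_time_s": [2.0], "peak_speed_mms": [13.0], "duration_s": [0.09],
            "trajectory_deg": [0.0], "posture_deg": [0.0], "posture_change_deg": [0.0],
        })
        ep = render_epoch(tbl, p, pad=2.0)
        traces = align_accelerations(ep, segment_bouts(ep), window=0.25)
        flat = np.abs(traces.time_s) > 0.15  # outside the bump's base width
        assert np.allclose(traces.linear_mmps2[flat], 0.0, atol=1e-9)
        # and the bump itself accelerates then decelerates around time 0
        assert traces.linear_mmps2.max() > 100.0
        assert traces.linear_mmps2.min() < -100.0

    def test_angular_peak_precedes_deceleration_onset(self):
        """Posture ramps ending 62.5 ms before peak speed put the angular-
        acceleration peak 62.5 ms before deceleration onset (+- one frame)."""
        p = preset("1wpf")
        bouts = generate_bout_table(p, 15, seed=3)
        ep = render_epoch(bouts, p, ramp_end_offset=0.0625)
        seg = segment_bouts(ep)
        traces = align_accelerations(ep, seg, window=0.25)
        # trace time 0 is the first frame of the peak pair, half a frame
        # before true peak speed
        t_peak_rel = traces.time_s - DT / 2
        t_star = t_peak_rel[np.argmax(np.abs(traces.angular_degps2))]
        assert t_star == pytest.approx(-0.0625, abs=DT)

    def test_pure_rotation_without_translation(self):
        n = 400
        t = np.arange(n) * DT
        posture = np.sin(t) * 20
        ep = make_epoch(t, np.zeros(n), np.zeros(n), posture)
        # no above-threshold motion: no bouts, so alignment must refuse
        with pytest.raises(ValueError):
            align_accelerations(ep, segment_bouts(ep), window=0.25)
        # but angular acceleration itself is nonzero while linear is zero
        assert np.allclose(compute_speed(ep), 0.0)
        assert np.max(np.abs(np.diff(posture, 2))) > 0


class TestFilterLightPhase:
    def ep_at(self, start, dur=10.0, epoch_id="e"):
        n = int(dur / DT)
        t = start + np.arange(n) * DT
        return make_epoch(t, np.zeros(n), np.zeros(n), np.zeros(n), epoch_id)

    def test_epoch_inside_exclusion_window_dropped(self):
        sched = LightSchedule(intervals=[(100.0, 50000.0)])
        out = filter_light_phase([self.ep_at(200.0)], sched)
        assert out == []

    def test_epoch_straddling_boundary_truncated(self):
        sched = LightSchedule(intervals=[(0.0, 50.0)])
        out = filter_light_phase([self.ep_at(44.0, dur=12.0)], sched)
        assert len(out) == 1
        assert out[0].time[-1] < 50.0
        assert out[0].duration >= 2.5
        # remaining piece shorter than 2.5 s is dropped
        out2 = filter_light_phase([self.ep_at(48.5, dur=12.0)], sched)
        assert out2 == []

    def test_no_dark_phase_keeps_everything(self):
        sched = LightSchedule(intervals=[(0.0, 86400.0)])
        eps = [self.ep_at(10.0), self.ep_at(1000.0)]
        assert len(filter_light_phase(eps, sched)) == 2

    def test_missing_schedule_passes_through_with_warning(self):
        eps = [self.ep_at(10.0)]
        with pytest.warns(UserWarning, match="schedule"):
            out = filter_light_phase(eps, None)
        assert out == eps
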