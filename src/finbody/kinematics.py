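"""Swim-bout segmentation and kinematic feature extraction.

Input is a *tracked epoch*: a continuous stretch of 40 Hz tracking of one
freely swimming larva in a vertical plane, giving centroid position (x
horizontal, z vertical, mm) and pitch-axis posture (deg, nose-up positive,
relative to horizontal).

Swim bouts are discrete propulsive events, defined as periods with centroid
speed exceeding 5 mm/s; consecutively detected bouts faster than 13 Hz are
merged into a single bout.  Per bout we measure:

* peak speed and its timing, from the largest displacement across two
  consecutive frames;
* trajectory: direction of that displacement relative to horizontal
  (deg, up positive);
* posture at peak speed (taken at the first frame of the peak pair);
* attack angle = trajectory - posture at peak (a larva pointing
  horizontally while moving straight up has an attack angle of 90 deg);
* posture change: pitch at 25 ms before peak minus pitch at 75 ms before
  peak, the steering contribution of the body;
* displacement (sum of frame-pair displacements above threshold) and
  duration (between interpolated 5 mm/s crossings).

Bouts with backwards trajectories (|trajectory| > 90 deg) are excluded and
counted.  Epochs shorter than 2.5 s are excluded from analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SPEED_THRESHOLD",
    "MERGE_INTERVAL",
    "MIN_EPOCH_DURATION",
    "TrackedEpoch",
    "SwimBout",
    "LightSchedule",
    "compute_speed",
    "segment_bouts",
    "bout_features",
    "bout_table",
    "interbout_features",
    "deviation_from_horizontal",
    "align_accelerations",
    "AccelerationTraces",
    "filter_light_phase",
]

SPEED_THRESHOLD = 5.0  # mm/s, bout definition
MERGE_INTERVAL = 1.0 / 13.0  # s; bouts detected faster than 13 Hz merge
MIN_EPOCH_DURATION = 2.5  # s; shorter epochs are excluded
_PC_EARLY = 0.075  # s before peak, start of posture-change window
_PC_LATE = 0.025  # s before peak, end of posture-change window


@dataclass
class TrackedEpoch:
    """One continuous tracking segment at a uniform frame rate."""

    epoch_id: str
    time: np.ndarray  # s
    x: np.ndarray  # mm, horizontal
    z: np.ndarray  # mm, vertical, up positive
    posture: np.ndarray  # deg, pitch, nose-up positive, in (-180, 180]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.posture = np.asarray(self.posture, dtype=float)
        n = self.time.size
        if not (self.x.size == self.z.size == self.posture.size == n):
            raise ValueError("time, x, z and posture must have equal length")
        if n >= 2:
            dts = np.diff(self.time)
            if np.any(dts <= 0):
                raise ValueError("time must be strictly increasing")
            if dts.max() - dts.min() > 0.01 * dts.mean():
                raise ValueError("non-uniform frame interval beyond 1% tolerance")
        if n and (self.posture.min() <= -180 or self.posture.max() > 180):
            raise ValueError("posture must lie in (-180, 180] deg")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def frame_interval(self) -> float:
        return float(np.mean(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class SwimBout:
    """One propulsive event and its kinematic features (angles deg, mm, s)."""

    epoch_id: str
    onset_time: float  # interpolated 5 mm/s crossing, rising
    offset_time: float  # interpolated 5 mm/s crossing, falling
    onset_frame_time: float  # first above-threshold displacement frame
    peak_speed: float
    peak_time: float
    peak_frame_index: int  # first frame of the max-displacement pair
    trajectory: float
    posture_at_peak: float
    attack_angle: float  # trajectory - posture_at_peak, exactly
    posture_change: float  # posture(-25 ms) - posture(-75 ms) before peak
    displacement: float
    duration: float
    valid_posture_change: bool


def compute_speed(epoch: TrackedEpoch) -> np.ndarray:
    """Per-frame speed: centroid displacement across frames / frame interval.

    ``speed[j]`` is the speed between frames j and j+1 (length n-1; the
    first frame has no defined speed).
    """
    if epoch.n_frames < 2:
        raise ValueError("need at least 2 frames to compute speed")
    dt = np.diff(epoch.time)
    disp = np.hypot(np.diff(epoch.x), np.diff(epoch.z))
    return disp / dt


def _speed_sample_times(epoch: TrackedEpoch) -> np.ndarray:
    """Displacement samples are attributed to frame-interval midpoints."""
    return 0.5 * (epoch.time[:-1] + epoch.time[1:])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, stop) sample indices."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def _interp_crossing(t0, v0, t1, v1, threshold):
    if v1 == v0:
        return t0
    return t0 + (threshold - v0) * (t1 - t0) / (v1 - v0)


def _features_for_run(
    epoch: TrackedEpoch,
    speed: np.ndarray,
    tmid: np.ndarray,
    js: int,
    je: int,
    threshold: float,
) -> SwimBout:
    if je < js:
        raise ValueError("malformed bout: empty frame run")
    t = epoch.time
    dt = epoch.frame_interval
    seg = speed[js : je + 1]
    jrel = int(np.argmax(seg))
    jstar = js + jrel
    peak_speed = float(speed[jstar])
    dx = epoch.x[jstar + 1] - epoch.x[jstar]
    dz = epoch.z[jstar + 1] - epoch.z[jstar]
    trajectory = float(np.degrees(np.arctan2(dz, dx)))
    posture_at_peak = float(epoch.posture[jstar])
    t_ref = float(t[jstar])

    # Interpolated threshold crossings on rising and falling phases.
    if js > 0:
        onset = _interp_crossing(tmid[js - 1], speed[js - 1], tmid[js], speed[js], threshold)
    else:
        onset = float(tmid[js])
    if je < speed.size - 1:
        offset = _interp_crossing(tmid[je], speed[je], tmid[je + 1], speed[je + 1], threshold)
    else:
        offset = float(tmid[je])

    # Posture change from 75 to 25 ms before peak speed.  At the native
    # 40 Hz rate these offsets are exact integer frame steps (-3, -1);
    # other rates interpolate posture linearly in time.
    native_40 = abs(dt - 0.025) < 1e-9
    valid = (t_ref - _PC_EARLY) >= t[0] - 1e-12
    if valid:
        if native_40:
            if jstar - 3 < 0:
                valid = False
                posture_change = float("nan")
            else:
                posture_change = float(epoch.posture[jstar - 1] - epoch.posture[jstar - 3])
        else:
            p_late = float(np.interp(t_ref - _PC_LATE, t, epoch.posture))
            p_early = float(np.interp(t_ref - _PC_EARLY, t, epoch.posture))
            posture_change = p_late - p_early
    else:
        posture_change = float("nan")

    above = seg > threshold
    displacement = float(np.sum(seg[above]) * dt)

    return SwimBout(
        epoch_id=epoch.epoch_id,
        onset_time=float(onset),
        offset_time=float(offset),
        onset_frame_time=float(t[js]),
        peak_speed=peak_speed,
        peak_time=float(tmid[jstar]),
        peak_frame_index=jstar,
        trajectory=trajectory,
        posture_at_peak=posture_at_peak,
        attack_angle=trajectory - posture_at_peak,
        posture_change=posture_change,
        displacement=displacement,
        duration=float(offset - onset),
        valid_posture_change=bool(valid),
    )


def segment_bouts(
    epoch: TrackedEpoch,
    threshold: float = SPEED_THRESHOLD,
    merge_interval: float = MERGE_INTERVAL,
    merge_on: Literal["onset", "offset"] = "onset",
    min_duration: float = MIN_EPOCH_DURATION,
    return_exclusions: bool = False,
):
    """Segment an epoch into swim bouts.

    Maximal runs of frames with speed above ``threshold`` are detected;
    runs whose inter-onset interval (or offset-to-onset gap, with
    ``merge_on='offset'``) is below ``merge_interval`` are merged.  Bouts
    with backwards trajectories (|trajectory| > 90 deg) are discarded and
    counted.  Epochs shorter than ``min_duration`` yield no bouts.
    """
    exclusions = {"short_epoch": 0, "backwards": 0}

    def _out(bouts):
        return (bouts, exclusions) if return_exclusions else bouts

    if epoch.duration < min_duration:
        logger.info(
            "epoch %s excluded: duration %.3f s < %.1f s",
            epoch.epoch_id, epoch.duration, min_duration,
        )
        exclusions["short_epoch"] = 1
        return _out([])

    speed = compute_speed(epoch)
    tmid = _speed_sample_times(epoch)
    runs = _runs(speed > threshold)
    if not runs:
        return _out([])

    merged: list[tuple[int, int]] = [runs[0]]
    for js, je in runs[1:]:
        pjs, pje = merged[-1]
        gap = tmid[js] - (tmid[pjs] if merge_on == "onset" else tmid[pje])
        if gap < merge_interval:
            merged[-1] = (pjs, je)
        else:
            merged.append((js, je))

    bouts = []
    for js, je in merged:
        bout = _features_for_run(epoch, speed, tmid, js, je, threshold)
        if abs(bout.trajectory) > 90.0:
            exclusions["backwards"] += 1
            continue
        bouts.append(bout)
    return _out(bouts)


def bout_features(epoch: TrackedEpoch, bout: SwimBout,
                  threshold: float = SPEED_THRESHOLD) -> SwimBout:
    """Recompute all kinematic features for a bout from its onset/offset.

    Useful to complete a bout whose interval is known but whose features
    are stale or missing.
    """
    speed = compute_speed(epoch)
    tmid = _speed_sample_times(epoch)
    inside = np.flatnonzero(
        (tmid >= bout.onset_time - 1e-12) & (tmid <= bout.offset_time + 1e-12)
        & (speed > threshold)
    )
    if inside.size < 1 or inside[-1] - inside[0] < 1:
        raise ValueError(
            f"malformed bout: fewer than 2 frames between "
            f"{bout.onset_time:.3f} and {bout.offset_time:.3f} s"
        )
    return _features_for_run(epoch, speed, tmid, int(inside[0]), int(inside[-1]), threshold)


def bout_table(bouts: Iterable[SwimBout]) -> pd.DataFrame:
    """Tabulate bouts with one row per bout (delimited-text friendly)."""
    rows = [
        {
            "epoch_id": b.epoch_id,
            "onset_time_s": b.onset_time,
            "offset_time_s": b.offset_time,
            "peak_time_s": b.peak_time,
            "peak_speed_mms": b.peak_speed,
            "trajectory_deg": b.trajectory,
            "posture_deg": b.posture_at_peak,
            "attack_angle_deg": b.attack_angle,
            "posture_change_deg": b.posture_change,
            "displacement_mm": b.displacement,
            "duration_s": b.duration,
            "valid_posture_change": b.valid_posture_change,
        }
        for b in bouts
    ]
    return pd.DataFrame(rows)


def interbout_features(bouts: Sequence[SwimBout], epoch: TrackedEpoch) -> pd.DataFrame:
    """Inter-bout metrics for successive bouts within one epoch.

    Instantaneous bout rate is the inverse of the interval between the
    first above-threshold frames of successive bouts; inter-bout duration
    is that period minus the earlier bout's duration; vertical displacement
    is z at the next onset minus z at the current offset.  A single bout
    yields an empty table.
    """
    cols = ["rate_hz", "interbout_duration_s", "interbout_dz_mm"]
    same = [b for b in bouts if b.epoch_id == epoch.epoch_id]
    if len(same) < 2:
        return pd.DataFrame(columns=cols)
    same = sorted(same, key=lambda b: b.onset_time)
    rows = []
    for a, b in zip(same[:-1], same[1:]):
        period = b.onset_frame_time - a.onset_frame_time
        z_next = float(np.interp(b.onset_time, epoch.time, epoch.z))
        z_cur = float(np.interp(a.offset_time, epoch.time, epoch.z))
        rows.append({
            "rate_hz": 1.0 / period,
            "interbout_duration_s": period - a.duration,
            "interbout_dz_mm": z_next - z_cur,
        })
    return pd.DataFrame(rows, columns=cols)


def deviation_from_horizontal(epochs) -> float:
    """Mean absolute pitch posture over all frames (deg).

    Accepts a single epoch or an iterable of epochs; the field's standard
    balance-performance summary.
    """
    if isinstance(epochs, TrackedEpoch):
        epochs = [epochs]
    postures = np.concatenate([e.posture for e in epochs])
    if postures.size == 0:
        raise ValueError("no frames to summarize")
    return float(np.mean(np.abs(postures)))


@dataclass
class AccelerationTraces:
    """Mean bout-aligned acceleration traces (time 0 = peak linear speed)."""

    time_s: np.ndarray
    linear_mmps2: np.ndarray
    angular_degps2: np.ndarray
    n_bouts: int
    n_skipped: int


def align_accelerations(
    epochs, bouts, window: float = 0.25
) -> AccelerationTraces:
    """Average linear and angular acceleration across bouts, aligned to peak.

    Linear acceleration is the first difference of speed over the frame
    interval; angular acceleration is the second difference of posture over
    the squared interval.  Bouts whose +-``window`` span exceeds the epoch
    bounds are skipped and counted.
    """
    if isinstance(epochs, TrackedEpoch):
        epochs = [epochs]
        bouts = [bouts]
    lin_sum = ang_sum = None
    n_used = n_skipped = 0
    half = None
    for epoch, epoch_bouts in zip(epochs, bouts):
        if not epoch_bouts:
            continue
        dt = epoch.frame_interval
        w = int(round(window / dt))
        half = w
        speed = compute_speed(epoch)
        lin = np.diff(speed) / dt  # sample j -> acceleration at frame j+1
        ang = np.diff(epoch.posture, 2) / dt**2  # sample i -> frame i+1
        for b in epoch_bouts:
            c = b.peak_frame_index
            if c - w < 1 or c + w > min(lin.size, ang.size):
                n_skipped += 1
                continue
            lw = lin[c - w - 1 : c + w]  # frames c-w .. c+w
            aw = ang[c - w - 1 : c + w]
            if lin_sum is None:
                lin_sum = np.zeros_like(lw)
                ang_sum = np.zeros_like(aw)
            lin_sum += lw
            ang_sum += aw
            n_used += 1
    if n_used == 0:
        raise ValueError("no bout had the full alignment window inside its epoch")
    dt_rel = window / half
    rel = np.arange(-half, half + 1) * dt_rel
    return AccelerationTraces(
        time_s=rel,
        linear_mmps2=lin_sum / n_used,
        angular_degps2=ang_sum / n_used,
        n_bouts=n_used,
        n_skipped=n_skipped,
    )


@dataclass
class LightSchedule:
    """Light-phase intervals of the recording, in seconds from its start.

    ``intervals`` lists (start, end) of each light phase.  An interval that
    starts after time 0 is treated as a dark-to-light transition, and the
    first ``exclusion_after_dark`` seconds following it are excluded to
    avoid light-onset transients.  Only the first ``analysis_window``
    seconds of the recording are analysed.
    """

    intervals: Sequence[tuple[float, float]]
    exclusion_after_dark: float = 2 * 3600.0
    analysis_window: float = 24 * 3600.0

    def kept_intervals(self) -> list[tuple[float, float]]:
        kept = []
        for start, end in self.intervals:
            eff = start + self.exclusion_after_dark if start > 0 else start
            eff_end = min(end, self.analysis_window)
            if eff < eff_end:
                kept.append((eff, eff_end))
        return kept


def filter_light_phase(
    epochs: Sequence[TrackedEpoch],
    schedule: LightSchedule | None,
    min_duration: float = MIN_EPOCH_DURATION,
) -> list[TrackedEpoch]:
    """Restrict epochs to analysable light-phase frames.

    Epochs straddling a boundary are truncated; resulting sub-epochs
    shorter than ``min_duration`` are dropped.  With no schedule, epochs
    pass through unchanged (with a warning).
    """
    if schedule is None:
        warnings.warn("no light schedule provided; keeping all epochs", stacklevel=2)
        return list(epochs)
    kept = schedule.kept_intervals()
    out: list[TrackedEpoch] = []
    for epoch in epochs:
        mask = np.zeros(epoch.n_frames, dtype=bool)
        for start, end in kept:
            mask |= (epoch.time >= start) & (epoch.time < end)
        pieces = _runs(mask)
        for n, (i0, i1) in enumerate(pieces):
            sub = TrackedEpoch(
                epoch_id=epoch.epoch_id if len(pieces) == 1 else f"{epoch.epoch_id}.{n}",
                time=epoch.time[i0 : i1 + 1],
                x=epoch.x[i0 : i1 + 1],
                z=epoch.z[i0 : i1 + 1],
                posture=epoch.posture[i0 : i1 + 1],
            )
            if sub.duration >= min_duration:
                out.append(sub)
    return out
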