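"""Synthetic swim generation.

Produces ground-truth bout tables with the statistical structure the
analysis assumes (Gaussian posture changes, attack angles coupled to
posture changes through a preset's coupling rule, near-Poisson bout
timing), and renders them into frame-level tracked epochs so the full
segmentation pipeline can be exercised without recorded video.

Rendering conventions
---------------------
* Each bout is a half-sine speed bump whose peak equals the bout's peak
  speed; the base width is chosen so that the time spent above the 5 mm/s
  detection threshold equals the bout's nominal duration.  Half-sines give
  smooth, analytically invertible threshold crossings.
* Bout peak times are snapped to frame-interval midpoints so that the
  maximal frame-pair displacement falls on a known frame pair and the
  rendered features are exactly recoverable by segmentation.
* Heading is fixed at the bout trajectory for the whole bump, so the
  measured trajectory at peak speed equals the commanded one.
* Posture ramps linearly into each bout at a rate of (posture change)/50 ms,
  ending by default at the first frame of the peak pair; the change
  measured between 75 and 25 ms before peak speed then equals the
  commanded posture change exactly.  Between bouts posture drifts linearly
  toward the next bout's ramp start.
* Between bouts the centroid sinks straight down at the preset's sink
  speed (< 5 mm/s, so inter-bout frames never trigger detection).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .kinematics import MERGE_INTERVAL, TrackedEpoch
from .presets import FinBiasPreset, SimPreset

__all__ = [
    "generate_bout_table",
    "generate_fin_bias_bouts",
    "render_epoch",
    "halfsine_width_above",
]

SPEED_FLOOR = 6.0  # mm/s; rendered peaks must clear the 5 mm/s threshold
MIN_INTERVAL = 0.55  # s; keeps rendered bouts non-overlapping / non-merging
_RAMP_RATE_WINDOW = 0.05  # s; posture-change window length (75 - 25 ms)

BOUT_COLUMNS = [
    "bout_id",
    "onset_time_s",
    "peak_time_s",
    "peak_speed_mms",
    "duration_s",
    "posture_change_deg",
    "attack_angle_deg",
    "posture_deg",
    "trajectory_deg",
]


def halfsine_width_above(peak: float, duration: float, threshold: float = 5.0) -> float:
    """Base width of a half-sine bump spending ``duration`` above threshold.

    A bump v(t) = peak * sin(pi t / w) exceeds ``threshold`` for
    w * (1 - 2/pi * asin(threshold/peak)); invert for w.
    """
    if peak <= threshold:
        raise ValueError(f"peak speed {peak} must exceed threshold {threshold}")
    frac = 1.0 - (2.0 / np.pi) * np.arcsin(threshold / peak)
    return duration / frac


def _snap_to_midframe(t: np.ndarray, dt: float) -> np.ndarray:
    """Snap times to the nearest frame-interval midpoint (n + 1/2) * dt."""
    return (np.floor(t / dt) + 0.5) * dt


def _peak_times(rng: np.random.Generator, preset: SimPreset, n: int,
                min_interval: float) -> np.ndarray:
    """Bout peak times: shifted-exponential intervals, snapped to the grid.

    Intervals are ``min_interval`` plus an exponential tail whose mean is
    chosen so the overall mean interval is 1/bout_rate (or just above the
    floor when the requested rate is too fast to honour).
    """
    tail_mean = max(1.0 / preset.bout_rate - min_interval, 0.05)
    intervals = min_interval + rng.exponential(tail_mean, size=n - 1) if n > 1 else np.array([])
    peaks = 0.5 + np.concatenate(([0.0], np.cumsum(intervals)))
    return _snap_to_midframe(peaks, 1.0 / preset.frame_rate)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = out <= floor
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= floor
    return out


def _assemble(preset: SimPreset, peaks, speeds, r, attack, posture) -> pd.DataFrame:
    trajectory = posture + attack  # defining identity of the attack angle
    return pd.DataFrame({
        "bout_id": np.arange(len(peaks)),
        "onset_time_s": peaks - preset.bout_duration / 2.0,
        "peak_time_s": peaks,
        "peak_speed_mms": speeds,
        "duration_s": np.full(len(peaks), float(preset.bout_duration)),
        "posture_change_deg": r,
        "attack_angle_deg": attack,
        "posture_deg": posture,
        "trajectory_deg": trajectory,
    }, columns=BOUT_COLUMNS)


def generate_bout_table(preset: SimPreset, n_bouts: int,
                        seed: int | None = None) -> pd.DataFrame:
    """Draw a ground-truth bout table from a preset.

    Posture changes are N(mean, sd); the attack angle is the coupling
    rule's expectation at that posture change plus N(0, attack_noise_sd);
    posture at peak speed is drawn from the baseline distribution;
    trajectory = posture + attack angle.  Onset times are spaced by
    near-exponential intervals truncated below the rendering/merge limit.
    Deterministic given (preset, n_bouts, seed).
    """
    preset.validate()
    if n_bouts < 1:
        raise ValueError(f"n_bouts must be >= 1, got {n_bouts}")
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    peaks = _peak_times(rng, preset, n_bouts, MIN_INTERVAL)
    speeds = _truncated_normal(rng, preset.peak_speed_mean, preset.peak_speed_sd,
                               SPEED_FLOOR, n_bouts)
    r = rng.normal(preset.posture_change_mean, preset.posture_change_sd, n_bouts)
    attack = np.asarray(preset.coupling.mean_attack(r), dtype=float)
    if preset.attack_noise_sd > 0:
        attack = attack + rng.normal(0.0, preset.attack_noise_sd, n_bouts)
    posture = rng.normal(preset.baseline_posture_mean, preset.baseline_posture_sd, n_bouts)
    return _assemble(preset, peaks, speeds, r, attack, posture)


def generate_fin_bias_bouts(preset: FinBiasPreset, n_bouts: int,
                            seed: int | None = None) -> pd.DataFrame:
    """Draw bouts from the generative fin-bias model.

    Each bout's Gaussian steering command s is split by the fin bias
    alpha: the body receives (1 - alpha) s as a posture change and the
    fins receive alpha * max(s, 0) as an attack angle (fins produce lift,
    i.e. upward steering, only).  The attack-angle : posture-change ratio
    therefore never exceeds alpha/(1 - alpha), and at alpha = 0 all attack
    angles are exactly 0.
    """
    preset.validate()
    if n_bouts < 1:
        raise ValueError(f"n_bouts must be >= 1, got {n_bouts}")
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    peaks = _peak_times(rng, preset, n_bouts, MIN_INTERVAL)
    speeds = _truncated_normal(rng, preset.peak_speed_mean, preset.peak_speed_sd,
                               SPEED_FLOOR, n_bouts)
    steer = rng.normal(0.0, preset.steer_magnitude_sd, n_bouts)
    r = (1.0 - preset.alpha) * steer
    attack = preset.alpha * np.maximum(steer, 0.0)
    posture = rng.normal(preset.baseline_posture_mean, preset.baseline_posture_sd, n_bouts)
    return _assemble(preset, peaks, speeds, r, attack, posture)


def render_epoch(
    bouts: pd.DataFrame,
    preset: SimPreset,
    epoch_id: str | None = None,
    threshold: float = 5.0,
    ramp_end_offset: float | None = None,
    ramp_duration: float = 0.0875,
    pad: float = 0.75,
) -> TrackedEpoch:
    """Render a ground-truth bout table into a frame-level tracked epoch.

    ``ramp_end_offset`` is how long before the bout's peak time the posture
    ramp ends; the default (half a frame) ends it exactly at the first
    frame of the peak displacement pair, making the measured posture change
    and posture-at-peak exact.  Increase it (e.g. to 0.0625 s) to emulate
    steering rotations that finish before thrust ends.
    """
    preset.validate()
    dt = 1.0 / preset.frame_rate
    if ramp_end_offset is None:
        ramp_end_offset = dt / 2.0

    peaks = _snap_to_midframe(np.asarray(bouts["peak_time_s"], float), dt)
    order = np.argsort(peaks)
    peaks = peaks[order]
    speeds = np.asarray(bouts["peak_speed_mms"], float)[order]
    durations = np.asarray(bouts["duration_s"], float)[order]
    trajs = np.radians(np.asarray(bouts["trajectory_deg"], float)[order])
    postures = np.asarray(bouts["posture_deg"], float)[order]
    r = np.asarray(bouts["posture_change_deg"], float)[order]

    if peaks.size > 1 and np.any(np.diff(peaks) < MERGE_INTERVAL):
        warnings.warn(
            "bout spacing below the 13 Hz merge limit: rendered bouts will "
            "merge downstream by design",
            stacklevel=2,
        )

    widths = np.array([halfsine_width_above(v, d, threshold)
                       for v, d in zip(speeds, durations)])
    t_end = peaks[-1] + max(pad, widths[-1])
    n_frames = int(np.ceil(t_end / dt)) + 1
    time = np.arange(n_frames) * dt

    # Analytic displacement of each half-sine bump within each frame interval.
    a = time[:-1]
    b = time[1:]
    dx = np.zeros(n_frames - 1)
    dz = np.zeros(n_frames - 1)
    covered = np.zeros(n_frames - 1)
    for tp, v, w, th in zip(peaks, speeds, widths, trajs):
        t0 = tp - w / 2.0
        lo = np.clip(a, t0, t0 + w)
        hi = np.clip(b, t0, t0 + w)
        disp = (v * w / np.pi) * (np.cos(np.pi * (lo - t0) / w)
                                  - np.cos(np.pi * (hi - t0) / w))
        dx += disp * np.cos(th)
        dz += disp * np.sin(th)
        covered += hi - lo
    # Inter-bout sinking: straight down at sink_speed whenever no bump is active.
    dz -= preset.sink_speed * np.clip(b - a - covered, 0.0, None)

    x = np.concatenate(([0.0], np.cumsum(dx)))
    z = np.concatenate(([0.0], np.cumsum(dz)))

    # Posture: linear pre-bout ramp at r / 50 ms ending ramp_end_offset
    # before the peak, with linear drift between bouts.
    knot_t: list[float] = []
    knot_p: list[float] = []
    for tp, p_end, ri in zip(peaks, postures, r):
        te = tp - ramp_end_offset
        ts = te - ramp_duration
        p_start = p_end - ri / _RAMP_RATE_WINDOW * ramp_duration
        for tt, pp in ((ts, p_start), (te, p_end)):
            if knot_t and tt <= knot_t[-1]:
                continue  # overlapping bouts: keep earlier knots
            knot_t.append(tt)
            knot_p.append(pp)
    posture_series = np.interp(time, knot_t, knot_p)

    return TrackedEpoch(
        epoch_id=epoch_id or f"{preset.label}-sim",
        time=time,
        x=x,
        z=z,
        posture=posture_series,
    )
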