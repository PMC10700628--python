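"""Per-cell motility statistics for run-and-tumble swimmers.

Implements the standard operator chain for reorientation analysis of
bacterial video-microscopy tracks:

1. positions smoothed with a second-order Savitzky-Golay filter (window
   5 frames);
2. swimming speed from positions averaged over a 9-frame window;
3. cells slower than 12 um/s on average classified non-motile;
4. reorientation events at time points where the direction change of the
   filtered track exceeds 25 degrees AND the filtered speed drops below 70%
   of the trajectory's mean speed, with events closer than 2 frames merged;
5. run times between events (boundary runs are censored lower bounds) and
   the per-cell reorientation frequency as the inverse mean run time.

All thresholds live on :class:`MotilityConfig` and default to the values
above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .calibration import Calibration
from .trajectories import TrajectorySet

__all__ = [
    "MotilityConfig",
    "ReorientationEvent",
    "RunSegment",
    "smooth_positions",
    "windowed_speed",
    "classify_motile",
    "detect_reorientations",
    "extract_runs",
    "reorientation_frequency",
    "population_tumble_rate",
    "summarize_trajectories",
]

log = logging.getLogger(__name__)


@dataclass
class MotilityConfig:
    """Thresholds of the motility/reorientation operators (units in names).

    ``angle_mode`` selects how "minimal absolute change in angle" is read:
    ``"pointwise"`` (default) applies the 25-degree threshold to the
    unsigned angle between successive filtered displacement vectors at each
    time point; ``"window_min"`` instead thresholds the minimum of those
    pointwise angles over ``angle_window`` frames, a stricter reading of the
    same criterion. ``include_censored_runs`` controls whether the censored
    first/last runs enter the per-cell mean run time (they do by default;
    both are lower bounds, so including them biases the frequency upward —
    see docs/methods.md).
    """

    sg_window: int = 5          # frames, Savitzky-Golay window
    sg_order: int = 2           # Savitzky-Golay polynomial order
    speed_window: int = 9       # frames, position-averaging window for speed
    nonmotile_speed: float = 12.0   # um/s
    angle_threshold: float = 25.0   # degrees
    speed_fraction: float = 0.70    # of trajectory-mean filtered speed
    min_event_gap: int = 2      # frames between distinct events
    min_track_frames: int = 10  # shorter tracks go to QC, not analysis
    angle_mode: str = "pointwise"   # "pointwise" | "window_min"
    angle_window: int = 3       # frames, for angle_mode="window_min"
    include_censored_runs: bool = True

    def validate(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        if self.speed_window % 2 == 0 or self.speed_window < 1:
            raise ValueError("speed_window must be odd and >= 1")
        if self.nonmotile_speed <= 0 or self.angle_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not (0 < self.speed_fraction <= 1):
            raise ValueError("speed_fraction must be in (0, 1]")
        if self.min_event_gap < 1:
            raise ValueError("min_event_gap must be >= 1 frame")
        if self.min_track_frames < max(self.sg_window, self.speed_window):
            raise ValueError(
                "min_track_frames must be >= max(sg_window, speed_window)")
        if self.angle_mode not in ("pointwise", "window_min"):
            raise ValueError("angle_mode must be 'pointwise' or 'window_min'")


@dataclass(frozen=True)
class ReorientationEvent:
    """A detected tumble: frame index, turn magnitude, relative speed dip."""

    frame: int
    angle_change: float      # degrees, > angle_threshold by construction
    speed_ratio: float       # filtered speed / trajectory-mean speed, < speed_fraction


@dataclass(frozen=True)
class RunSegment:
    """A run between reorientation events; boundary runs are censored."""

    t_start: float
    t_end: float
    censored_start: bool
    censored_end: bool

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# smoothing and speed
# ---------------------------------------------------------------------------

def smooth_positions(xy: np.ndarray, config: MotilityConfig) -> np.ndarray:
    """Savitzky-Golay filter both coordinates of an (n, 2) position array.

    Endpoints are handled by evaluating the polynomial fitted to the first/
    last window (scipy's ``mode="interp"``), so trajectories that are exact
    polynomials up to ``sg_order`` are reproduced exactly everywhere.
    """
    config.validate()
    xy = np.asarray(xy, dtype=np.float64)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array, got {xy.shape}")
    if len(xy) < config.sg_window:
        raise ValueError(
            f"trajectory of {len(xy)} frames is shorter than sg_window="
            f"{config.sg_window}")
    return savgol_filter(xy, config.sg_window, config.sg_order,
                         axis=0, mode="interp")


def windowed_speed(xy_um: np.ndarray, dt: float, config: MotilityConfig) -> np.ndarray:
    """Per-frame swimming speed from window-averaged positions, in um/s.

    Positions are boxcar-averaged over ``speed_window`` frames; speeds are
    the displacements between consecutive window means divided by the frame
    interval. Returns ``n - speed_window`` samples for an ``n``-frame track.
    """
    config.validate()
    if dt <= 0:
        raise ValueError("dt must be > 0 (missing calibration?)")
    xy_um = np.asarray(xy_um, dtype=np.float64)
    w = config.speed_window
    if len(xy_um) < w + 1:
        raise ValueError(
            f"trajectory of {len(xy_um)} frames too short for speed_window={w}")
    kernel = np.full(w, 1.0 / w)
    ax = np.convolve(xy_um[:, 0], kernel, mode="valid")
    ay = np.convolve(xy_um[:, 1], kernel, mode="valid")
    return np.hypot(np.diff(ax), np.diff(ay)) / dt


def classify_motile(mean_speed: float, config: MotilityConfig | None = None) -> bool:
    """Motile iff the average speed is not below the non-motile cutoff.

    The cutoff is strict: a cell at exactly 12 um/s is motile ("less than
    12 um/s" defines non-motile).
    """
    cutoff = (config or MotilityConfig()).nonmotile_speed
    return not (mean_speed < cutoff)


# ---------------------------------------------------------------------------
# reorientation detection
# ---------------------------------------------------------------------------

def detect_reorientations(
    xy_smooth: np.ndarray,
    dt: float,
    config: MotilityConfig,
    frames: np.ndarray | None = None,
) -> list[ReorientationEvent]:
    """Detect tumbles on a smoothed trajectory.

    At each interior time point the unsigned angle between the incoming and
    outgoing filtered displacement vectors is compared with
    ``angle_threshold``, and the local filtered speed (mean of the two
    adjacent segment speeds) with ``speed_fraction`` times the trajectory's
    mean filtered speed; both must be exceeded/undershot for an event.
    Points with a zero-length displacement have no defined angle and are
    skipped (logged). Events closer than ``min_event_gap`` frames are merged
    keeping the earliest.
    """
    config.validate()
    xy = np.asarray(xy_smooth, dtype=np.float64)
    n = len(xy)
    if n < 3:
        return []
    if frames is None:
        frames = np.arange(n)

    d = np.diff(xy, axis=0)                      # (n-1, 2) segment vectors
    seg_len = np.hypot(d[:, 0], d[:, 1])
    seg_speed = seg_len / dt
    mean_speed = float(seg_speed.mean())
    if mean_speed == 0:
        return []

    # pointwise unsigned angle between successive segments, at points 1..n-2
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (d[:-1] * d[1:]).sum(axis=1) / (seg_len[:-1] * seg_len[1:])
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    defined = (seg_len[:-1] > 0) & (seg_len[1:] > 0)
    n_undefined = int((~defined).sum())
    if n_undefined:
        log.debug("skipped %d points with zero-length displacement", n_undefined)

    if config.angle_mode == "window_min":
        half = config.angle_window // 2
        padded = np.where(defined, angle, np.inf)
        crit_angle = np.array([
            np.min(padded[max(i - half, 0):i + half + 1])
            for i in range(len(angle))
        ])
        crit_angle = np.where(np.isfinite(crit_angle), crit_angle, np.nan)
    else:
        crit_angle = np.where(defined, angle, np.nan)

    point_speed = 0.5 * (seg_speed[:-1] + seg_speed[1:])
    speed_ratio = point_speed / mean_speed
    is_event = (crit_angle > config.angle_threshold) & \
               (speed_ratio < config.speed_fraction)
    is_event &= ~np.isnan(crit_angle)

    events: list[ReorientationEvent] = []
    last_kept: int | None = None
    for i in np.flatnonzero(is_event):
        frame = int(frames[i + 1])               # point i sits at sample i+1
        if last_kept is not None and frame - last_kept < config.min_event_gap:
            continue                             # merge: keep the earliest
        events.append(ReorientationEvent(
            frame=frame,
            angle_change=float(crit_angle[i]),
            speed_ratio=float(speed_ratio[i]),
        ))
        last_kept = frame
    return events


# ---------------------------------------------------------------------------
# runs and frequency
# ---------------------------------------------------------------------------

def extract_runs(
    t_start: float,
    t_end: float,
    event_times: list[float],
) -> list[RunSegment]:
    """Split a trajectory's time span into runs at the given event times.

    Interior runs lie between consecutive events; the first (start to first
    event) and last (last event to end) segments are censored lower-bound
    estimates. With no events the whole span is one doubly-censored run.
    Zero-duration segments (events at the boundary or coincident) are
    dropped.
    """
    times = sorted(event_times)
    if any(t < t_start or t > t_end for t in times):
        raise ValueError("event times must lie within [t_start, t_end]")
    bounds = [t_start] + times + [t_end]
    runs = []
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if b - a <= 0:
            continue
        runs.append(RunSegment(
            t_start=a,
            t_end=b,
            censored_start=(k == 0),
            censored_end=(k == len(bounds) - 2),
        ))
    return runs


def reorientation_frequency(
    runs: list[RunSegment],
    include_censored: bool = True,
) -> float:
    """Per-cell reorientation frequency: inverse of the mean run time (1/s).

    Censored boundary runs are included by default (they are lower bounds on
    the true run time, so the resulting frequency is an upper-bound-biased
    estimate — in particular a track with no events at all yields
    ``1 / track duration``). With ``include_censored=False`` only interior
    runs count, and a track without interior runs has undefined frequency
    (NaN).
    """
    if not runs:
        raise ValueError("need at least one run segment")
    durations = [
        r.duration for r in runs
        if include_censored or not (r.censored_start or r.censored_end)
    ]
    if not durations:
        return float("nan")
    mean = float(np.mean(durations))
    if mean <= 0:
        raise ValueError("mean run duration must be > 0")
    return 1.0 / mean


def population_tumble_rate(summary: pd.DataFrame) -> float:
    """Population-level event rate: total events / total observed time (1/s).

    Computed over motile cells only. Unlike the per-cell inverse-mean-run
    frequency this estimator is unbiased for the underlying Poisson
    reorientation rate (event counts are Poisson in the observation time),
    so it is the quantity to use for tumble-rate recovery.
    """
    m = summary[summary["motile"]]
    total_t = m["duration_s"].sum()
    if total_t <= 0:
        raise ValueError("no observed time among motile cells")
    return float(m["n_events"].sum() / total_t)


# ---------------------------------------------------------------------------
# per-cell summaries
# ---------------------------------------------------------------------------

def summarize_trajectories(
    trajectories: TrajectorySet,
    config: MotilityConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full motility chain on every trajectory.

    Returns ``(summary, events, qc)``:

    * ``summary`` — one row per analysed cell: ``particle``, ``n_frames``,
      ``duration_s``, ``mean_speed_um_s``, ``motile``, ``n_events``,
      ``mean_run_s``, ``reorientation_hz``. Non-motile cells keep their
      speed (for speed distributions) but have NaN reorientation statistics.
    * ``events`` — one row per detected reorientation:``particle``,
      ``frame``, ``t_s``, ``angle_change_deg``, ``speed_ratio``.
    * ``qc`` — counts of analysed / dropped-short tracks.
    """
    config = config or MotilityConfig()
    config.validate()
    cal: Calibration = trajectories.calibration
    dt = cal.dt

    min_frames = max(config.min_track_frames, config.sg_window,
                     config.speed_window + 1)
    sum_rows, ev_rows = [], []
    n_short = 0
    for pid, g in trajectories:
        n = len(g)
        if n < min_frames:
            n_short += 1
            log.debug("track %s dropped: %d < %d frames", pid, n, min_frames)
            continue
        xy = g[["x_um", "y_um"]].to_numpy()
        frames = g["frame"].to_numpy()
        speeds = windowed_speed(xy, dt, config)
        mean_speed = float(speeds.mean())
        motile = classify_motile(mean_speed, config)

        n_events: float = np.nan
        mean_run: float = np.nan
        freq: float = np.nan
        if motile:
            smooth = smooth_positions(xy, config)
            events = detect_reorientations(smooth, dt, config, frames=frames)
            t0, t1 = frames[0] * dt, frames[-1] * dt
            runs = extract_runs(t0, t1, [e.frame * dt for e in events])
            n_events = len(events)
            freq = reorientation_frequency(
                runs, include_censored=config.include_censored_runs)
            mean_run = (1.0 / freq) if freq and not np.isnan(freq) else np.nan
            for e in events:
                ev_rows.append({
                    "particle": pid, "frame": e.frame, "t_s": e.frame * dt,
                    "angle_change_deg": e.angle_change,
                    "speed_ratio": e.speed_ratio,
                })
        sum_rows.append({
            "particle": pid,
            "n_frames": n,
            "duration_s": (frames[-1] - frames[0]) * dt,
            "mean_speed_um_s": mean_speed,
            "motile": motile,
            "n_events": n_events,
            "mean_run_s": mean_run,
            "reorientation_hz": freq,
        })

    summary = pd.DataFrame(sum_rows)
    events_df = pd.DataFrame(
        ev_rows, columns=["particle", "frame", "t_s", "angle_change_deg",
                          "speed_ratio"])
    qc = {
        "n_tracks_in": len(trajectories),
        "n_tracks_analysed": len(summary),
        "n_tracks_too_short": n_short,
        "min_track_frames": int(min_frames),
    }
    return summary, events_df, qc
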