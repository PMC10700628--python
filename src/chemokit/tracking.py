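"""Spot detection, linking and drift correction for swimming-cell videos.

The stage mirrors the standard video-microscopy workflow for motile marine
bacteria: per-pixel median background subtraction over the whole video,
local-maximum spot detection with sub-pixel centroid refinement, frame-to-
frame linking as a gated minimum-cost bipartite assignment (maximum
displacement per frame 31 px, minimum separation between particles 51 px at
0.326 um/pixel by default), and ensemble-median drift correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .calibration import Calibration
from .trajectories import TrajectorySet

__all__ = [
    "TrackingConfig",
    "median_background",
    "subtract_background",
    "detect_spots",
    "link",
    "correct_drift",
    "track_stack",
]


@dataclass
class TrackingConfig:
    """Detection and linking parameters.

    ``max_displacement`` (px/frame) gates the linker; the default 31 px
    corresponds to roughly 200 um/s at typical calibration. Any two reported
    detections in a frame are at least ``min_separation`` px apart (default
    51), keeping the brighter one on conflict. ``detect_threshold`` is read
    per ``threshold_mode``: ``"sigma"`` (default) thresholds at
    ``mean + k * std`` of the background-subtracted frame — robust to the
    noise level without tuning; ``"quantile"`` at a per-frame intensity
    quantile; ``"absolute"`` at a fixed intensity. ``memory`` frames of
    disappearance are tolerated before a track is closed (default 0: no gap
    closing). Tracks shorter than ``min_track_length`` frames are discarded.
    """

    max_displacement: float = 31.0     # px / frame
    min_separation: float = 51.0       # px
    detect_threshold: float = 10.0     # sigmas above the frame mean by default
    threshold_mode: str = "sigma"      # "sigma" | "quantile" | "absolute"
    memory: int = 0                    # frames a particle may vanish
    min_track_length: int = 1          # frames
    refine_radius: int = 3             # px window for centroid refinement
    assignment: str = "optimal"        # "optimal" | "greedy"

    def validate(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.threshold_mode not in ("sigma", "quantile", "absolute"):
            raise ValueError(
                "threshold_mode must be 'sigma', 'quantile' or 'absolute'")
        if self.threshold_mode == "quantile" and not (0 < self.detect_threshold < 1):
            raise ValueError("quantile detect_threshold must be in (0, 1)")
        if self.threshold_mode == "sigma" and self.detect_threshold <= 0:
            raise ValueError("sigma detect_threshold must be > 0")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")
        if self.assignment not in ("optimal", "greedy"):
            raise ValueError("assignment must be 'optimal' or 'greedy'")


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def median_background(stack: np.ndarray) -> np.ndarray:
    """Per-pixel median image over the entire video.

    Requires at least 3 frames (the median of fewer is degenerate).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a (T, H, W) stack, got shape {stack.shape}")
    if stack.shape[0] < 3:
        raise ValueError("median background needs >= 3 frames")
    return np.median(stack, axis=0)


def subtract_background(stack: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Subtract a background image, clamping at zero.

    Integer stacks keep their dtype (unsigned output, clipped at 0); float
    stacks are clipped at 0 in float.
    """
    stack = np.asarray(stack)
    residual = stack.astype(np.float64) - np.asarray(background, dtype=np.float64)
    residual = np.clip(residual, 0, None)
    if np.issubdtype(stack.dtype, np.integer):
        info = np.iinfo(stack.dtype)
        return np.clip(np.round(residual), 0, info.max).astype(stack.dtype)
    return residual


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _refine_centroid(frame: np.ndarray, y: int, x: int, radius: int) -> tuple[float, float]:
    """Intensity-weighted centroid in a (2r+1)^2 window around a peak."""
    H, W = frame.shape
    y0, y1 = max(y - radius, 0), min(y + radius + 1, H)
    x0, x1 = max(x - radius, 0), min(x + radius + 1, W)
    win = frame[y0:y1, x0:x1].astype(np.float64)
    total = win.sum()
    if total <= 0:
        return float(y), float(x)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float((yy * win).sum() / total), float((xx * win).sum() / total)


def detect_spots(frame: np.ndarray, config: TrackingConfig) -> pd.DataFrame:
    """Detect bright spots in one background-subtracted frame.

    Local maxima above the detection threshold are refined to sub-pixel
    intensity-weighted centroids; any two reported positions are at least
    ``min_separation`` px apart (brighter wins on conflict). Returns a table
    with columns ``x``, ``y``, ``intensity`` (possibly empty).
    """
    config.validate()
    frame = np.asarray(frame, dtype=np.float64)
    if config.threshold_mode == "quantile":
        thr = float(np.quantile(frame, config.detect_threshold))
        thr = max(thr, float(frame.min()) + 1e-12)   # blank frame -> no peaks
    elif config.threshold_mode == "sigma":
        thr = float(frame.mean() + config.detect_threshold * frame.std())
        thr = max(thr, float(frame.min()) + 1e-12)
    else:
        thr = float(config.detect_threshold)

    peaks = peak_local_max(
        frame,
        min_distance=max(int(np.ceil(config.min_separation)), 1),
        threshold_abs=thr,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return pd.DataFrame(columns=["x", "y", "intensity"])

    rows = []
    for y, x in peaks:
        yc, xc = _refine_centroid(frame, int(y), int(x), config.refine_radius)
        rows.append((xc, yc, float(frame[y, x])))
    det = pd.DataFrame(rows, columns=["x", "y", "intensity"])
    det = det.sort_values("intensity", ascending=False).reset_index(drop=True)

    # re-enforce Euclidean separation on the refined positions, brighter first
    kept: list[int] = []
    xy = det[["x", "y"]].to_numpy()
    for i in range(len(det)):
        if all(np.hypot(*(xy[i] - xy[j])) >= config.min_separation for j in kept):
            kept.append(i)
    det = det.iloc[kept].sort_values(["y", "x"]).reset_index(drop=True)
    return det


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _assign_frame(
    prev_xy: np.ndarray,
    prev_gap: np.ndarray,
    new_xy: np.ndarray,
    max_disp: float,
    mode: str,
) -> list[tuple[int, int]]:
    """Match existing track ends to new detections under the displacement gate.

    The gate scales with the number of skipped frames (``prev_gap``). The
    optimal mode maximises the number of gated links, then minimises the
    total squared displacement; the greedy mode links nearest pairs first.
    Returns (track index, detection index) pairs.
    """
    n, m = len(prev_xy), len(new_xy)
    if n == 0 or m == 0:
        return []
    d2 = ((prev_xy[:, None, :] - new_xy[None, :, :]) ** 2).sum(axis=2)
    limit2 = (max_disp * prev_gap[:, None].astype(np.float64)) ** 2
    feasible = d2 <= limit2

    if mode == "greedy":
        pairs = []
        order = np.argsort(d2, axis=None, kind="stable")
        used_t: set[int] = set()
        used_d: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), m)
            if i in used_t or j in used_d or not feasible[i, j]:
                continue
            pairs.append((i, j))
            used_t.add(i)
            used_d.add(j)
        return sorted(pairs)

    # optimal: square matrix with "unmatched" pads. 2B must exceed the total
    # feasible cost of any matching so that more links always win (a single
    # link's gate bound is not enough: rearrangements can trade several
    # links' costs at once); INF forbids infeasible links.
    B = float(min(n, m) * limit2.max()) + 1.0
    INF = (n + m + 1) * B * 10.0
    size = n + m
    cost = np.full((size, size), INF)
    cost[:n, :m] = np.where(feasible, d2, INF)
    cost[:n, m:] = INF
    cost[n:, :m] = INF
    np.fill_diagonal(cost[:n, m:], B)       # track i unmatched
    np.fill_diagonal(cost[n:, :m], B)       # detection j unmatched
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return sorted(
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and feasible[i, j]
    )


def link(
    detections: pd.DataFrame,
    config: TrackingConfig,
    calibration: Calibration | None = None,
) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    ``detections`` must have columns ``frame``, ``x``, ``y`` (pixels).
    Frame-to-frame assignment maximises the number of links whose
    displacement is within ``max_displacement`` px/frame and, among those,
    minimises the total squared displacement. Unmatched detections open new
    trajectories; a track missing for more than ``memory`` frames is closed.
    Ties are broken deterministically (detections processed in sorted order).
    """
    config.validate()
    if calibration is None:
        calibration = Calibration()
    req = {"frame", "x", "y"}
    if not req <= set(detections.columns):
        raise ValueError(f"detections need columns {sorted(req)}")

    det = detections.sort_values(["frame", "y", "x"]).reset_index(drop=True)
    next_id = 0
    # active track state: id, last frame, last xy
    act_id: list[int] = []
    act_frame: list[int] = []
    act_xy: list[np.ndarray] = []
    out_rows: list[tuple[int, int, float, float]] = []

    for frame, group in det.groupby("frame", sort=True):
        frame = int(frame)
        new_xy = group[["x", "y"]].to_numpy(dtype=np.float64)

        # retire tracks outside the memory window
        keep = [k for k, f in enumerate(act_frame) if frame - f <= config.memory + 1]
        act_id = [act_id[k] for k in keep]
        act_frame = [act_frame[k] for k in keep]
        act_xy = [act_xy[k] for k in keep]

        gaps = np.array([frame - f for f in act_frame], dtype=int)
        prev = np.array(act_xy) if act_xy else np.empty((0, 2))
        pairs = _assign_frame(prev, gaps, new_xy, config.max_displacement,
                              config.assignment)
        matched_dets = {j for _, j in pairs}
        for i, j in pairs:
            act_frame[i] = frame
            act_xy[i] = new_xy[j]
            out_rows.append((act_id[i], frame, new_xy[j, 0], new_xy[j, 1]))
        for j in range(len(new_xy)):
            if j not in matched_dets:
                act_id.append(next_id)
                act_frame.append(frame)
                act_xy.append(new_xy[j])
                out_rows.append((next_id, frame, new_xy[j, 0], new_xy[j, 1]))
                next_id += 1

    df = pd.DataFrame(out_rows, columns=["particle", "frame", "x", "y"])
    if len(df):
        lengths = df.groupby("particle")["frame"].size()
        keep_ids = lengths[lengths >= config.min_track_length].index
        df = df[df["particle"].isin(keep_ids)].reset_index(drop=True)
    df["x_um"] = calibration.px_to_um(df["x"])
    df["y_um"] = calibration.px_to_um(df["y"])
    return TrajectorySet(df[["particle", "frame", "x_um", "y_um"]], calibration)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def correct_drift(trajectories: TrajectorySet) -> TrajectorySet:
    """Remove bulk fluid motion via the ensemble-median displacement.

    Per consecutive frame pair, the drift step is the median over all
    particles present in both frames of their displacement; the cumulative
    sum is subtracted from every position. With fewer than two trajectories
    overlapping in time the input is returned unchanged with a warning.
    """
    df = trajectories.data
    if len(trajectories) < 2:
        warnings.warn("drift correction skipped: fewer than 2 trajectories",
                      stacklevel=2)
        return trajectories
    frame_counts = df.groupby("frame")["particle"].size()
    if (frame_counts < 2).all():
        warnings.warn("drift correction skipped: no frame holds 2 overlapping "
                      "trajectories", stacklevel=2)
        return trajectories

    frames = np.sort(df["frame"].unique())
    wide_x = df.pivot(index="frame", columns="particle", values="x_um").reindex(frames)
    wide_y = df.pivot(index="frame", columns="particle", values="y_um").reindex(frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN frame pairs
        step_x = np.nanmedian(wide_x.diff().to_numpy(), axis=1)
        step_y = np.nanmedian(wide_y.diff().to_numpy(), axis=1)
    step_x = np.nan_to_num(step_x)
    step_y = np.nan_to_num(step_y)
    drift = pd.DataFrame(
        {"dx": np.cumsum(step_x), "dy": np.cumsum(step_y)}, index=frames)

    out = df.copy()
    out["x_um"] = out["x_um"] - drift["dx"].reindex(out["frame"]).to_numpy()
    out["y_um"] = out["y_um"] - drift["dy"].reindex(out["frame"]).to_numpy()
    return TrajectorySet(out, trajectories.calibration,
                         trajectories.events, trajectories.ground_truth)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def track_stack(
    stack: np.ndarray,
    config: TrackingConfig,
    calibration: Calibration | None = None,
    drift_correct: bool = True,
) -> TrajectorySet:
    """Full tracking pipeline: median background -> detect -> link -> drift.

    ``stack`` is a (T, H, W) array or an :class:`~chemokit.synthetic.ImageStack`
    (whose calibration is used unless one is given explicitly).
    """
    from .synthetic import ImageStack   # local import to avoid a cycle

    if isinstance(stack, ImageStack):
        if calibration is None:
            calibration = stack.calibration
        stack = stack.frames
    config.validate()
    bg = median_background(stack)
    residual = subtract_background(stack, bg)
    per_frame = []
    for k in range(residual.shape[0]):
        det = detect_spots(residual[k], config)
        det["frame"] = k
        per_frame.append(det)
    detections = pd.concat(per_frame, ignore_index=True)
    trajs = link(detections, config, calibration)
    if drift_correct and len(trajs) >= 2:
        trajs = correct_drift(trajs)
    return trajs
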