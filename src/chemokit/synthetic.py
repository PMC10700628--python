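"""Synthetic ground-truth data for every pipeline stage.

Four generators:

* :func:`simulate_run_and_tumble` — run-and-tumble swimmers (Poisson tumbling,
  heading persistence between tumbles, localisation noise, optional uniform
  drift and a non-motile subpopulation), sampled at video frame rate, with the
  true tumble-event log returned alongside the positions.
* :func:`render_video` — grayscale image stacks (Gaussian spots over a
  background) from any trajectory set, the input of the tracking stage.
* :func:`generate_isca_counts` — pooled per-well cell concentrations for an
  in situ chemotaxis assay (ISCA) plate design with known treatment effects.
* :func:`generate_environment_table` — a day x covariate table in which chosen
  variables are rank-correlated with an emitted chemotactic-index series.

All generators are deterministic given their seed; each cell / plate draws
from its own child stream of the root seed, so enlarging an experiment never
perturbs the entities already simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import Calibration
from .trajectories import TrajectorySet

__all__ = [
    "SimulationParams",
    "ImagingParams",
    "IscaDesign",
    "ImageStack",
    "simulate_run_and_tumble",
    "render_video",
    "generate_isca_counts",
    "generate_environment_table",
]


# ---------------------------------------------------------------------------
# parameter objects
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Ground-truth knobs of the run-and-tumble simulator.

    Motile cells swim at a per-cell speed ~ Normal(``mean_speed``,
    ``speed_sd``) with a constant heading between tumbles. Tumbles arrive as
    a Poisson process at ``tumble_rate``; each multiplies the speed by
    ``tumble_speed_fraction`` for ``tumble_duration`` frames and then
    redirects the heading by a wrapped-normal angle of width
    ``turn_angle_sd`` (degrees). ``turn_angle_min`` optionally floors the
    turn magnitude so that every simulated tumble is detectable by an
    angle-threshold detector — a validation convenience, not a biological
    claim. A ``nonmotile_fraction`` of cells only jitter about their start
    position. Drift is added uniformly to all cells, Gaussian localisation
    noise last.
    """

    n_cells: int = 100
    duration: float = 30.0          # s
    frame_rate: float = 30.0        # Hz (typical video-microscopy: 25-30)
    mean_speed: float = 40.0        # um/s
    speed_sd: float = 8.0           # um/s
    tumble_rate: float = 0.5        # events / s (Poisson)
    turn_angle_sd: float = 90.0     # deg, wrapped-normal width of turn angles
    turn_angle_min: float = 0.0     # deg, floor on |turn angle| (0 = none)
    tumble_speed_fraction: float = 0.2   # speed multiplier during a tumble
    tumble_duration: int = 2        # frames
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # um/s
    noise_sd: float = 0.1           # um per coordinate
    nonmotile_fraction: float = 0.0
    nonmotile_jitter_sd: float = 0.15   # um
    arena: tuple[float, float] = (500.0, 500.0)  # um (width, height)
    boundary: str = "none"          # "none" | "reflect"
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "duration": self.duration, "frame_rate": self.frame_rate,
            "mean_speed": self.mean_speed, "speed_sd": self.speed_sd,
            "tumble_rate": self.tumble_rate, "turn_angle_sd": self.turn_angle_sd,
            "turn_angle_min": self.turn_angle_min,
            "tumble_speed_fraction": self.tumble_speed_fraction,
            "noise_sd": self.noise_sd,
            "nonmotile_fraction": self.nonmotile_fraction,
            "nonmotile_jitter_sd": self.nonmotile_jitter_sd,
        }
        for name, v in scalars.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        for name, v in (("drift_velocity", self.drift_velocity), ("arena", self.arena)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for name in ("speed_sd", "tumble_rate", "turn_angle_sd", "noise_sd",
                     "nonmotile_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tumble_speed_fraction", "nonmotile_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tumble_duration < 1:
            raise ValueError("tumble_duration must be >= 1 frame")
        if self.boundary not in ("none", "reflect"):
            raise ValueError(f"boundary must be 'none' or 'reflect', got {self.boundary!r}")


@dataclass
class ImagingParams:
    """Camera / optics model for rendering trajectories into image stacks.

    ``frame_shape`` is numpy-style (height, width); the default matches a
    2044 x 2048 CMOS sensor at 0.326 um/pixel and scales down freely. Spots
    are isotropic Gaussians of width ``psf_sigma`` pixels and peak height
    ``spot_amplitude`` added onto ``background_level`` (plus an optional
    static ``background_pattern``), with Gaussian read noise of sd
    ``noise_sd``. Positions outside the field of view are dropped or clipped
    to the frame edge per ``out_of_frame``.
    """

    pixel_size_um: float = 0.326
    frame_shape: tuple[int, int] = (2044, 2048)   # (height, width), scalable
    psf_sigma: float = 1.5            # px
    spot_amplitude: float = 4000.0    # intensity units
    background_level: float = 400.0   # intensity units
    background_pattern: np.ndarray | None = None
    noise_sd: float = 0.0             # intensity units
    out_of_frame: str = "drop"        # "drop" | "clip"
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if min(self.frame_shape) <= 0:
            raise ValueError("frame_shape must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.out_of_frame not in ("drop", "clip"):
            raise ValueError("out_of_frame must be 'drop' or 'clip'")
        if self.background_pattern is not None:
            if self.background_pattern.shape != tuple(self.frame_shape):
                raise ValueError("background_pattern shape must equal frame_shape")
            if not np.all(np.isfinite(self.background_pattern)):
                raise ValueError("background_pattern must be finite")


@dataclass
class IscaDesign:
    """Design of a simulated ISCA experiment.

    Each plate carries one row of ``wells_per_treatment`` wells per
    treatment; well contents are pooled before counting, so the generator
    draws one pooled concentration per plate x treatment. ``treatments``
    maps treatment name to the multiplicative effect on the control mean
    concentration; the control treatment (``control_name``) always has
    effect exactly 1 and is added automatically if absent.

    Counts follow a negative binomial with mean ``m = control_mean * effect
    * sample_volume_ml`` and variance ``m * (1 + dispersion * m)``;
    ``dispersion`` -> 0 approaches Poisson counting statistics, and
    ``dispersion == 0`` is the deterministic limit (counts equal their
    rounded means). The default 4e-4 gives ~20% between-plate CV at the
    default concentration, typical of biological ISCA replicates.
    """

    n_plates: int = 3
    wells_per_treatment: int = 5
    treatments: list[tuple[str, float]] = field(default_factory=list)
    control_name: str = "FSW"
    control_mean: float = 1.0e5       # cells / mL
    dispersion: float = 4.0e-4        # NB overdispersion alpha
    sample_volume_ml: float = 0.03    # volume counted by the cytometer
    seed: int = 0

    def resolved_treatments(self) -> list[tuple[str, float]]:
        tr = list(self.treatments)
        names = [t[0] for t in tr]
        if self.control_name not in names:
            tr = [(self.control_name, 1.0)] + tr
        return tr

    def validate(self) -> None:
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")
        if self.wells_per_treatment < 1:
            raise ValueError("wells_per_treatment must be >= 1")
        if self.control_mean <= 0:
            raise ValueError("control_mean must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.sample_volume_ml <= 0:
            raise ValueError("sample_volume_ml must be > 0")
        for name, eff in self.resolved_treatments():
            if eff < 0 or not np.isfinite(eff):
                raise ValueError(f"effect size of {name!r} must be finite and >= 0")
            if name == self.control_name and eff != 1.0:
                raise ValueError("control treatment effect size must be exactly 1")


@dataclass
class ImageStack:
    """A rendered grayscale video: uint16 frames plus acquisition metadata."""

    frames: np.ndarray                 # (T, H, W) uint16
    pixel_size_um: float
    frame_rate_hz: float

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um, self.frame_rate_hz)

    def save_tiff(self, path: str | Path) -> None:
        """Write a multi-page 16-bit grayscale TIFF with metadata tags."""
        tifffile.imwrite(
            Path(path),
            self.frames,
            photometric="minisblack",
            metadata={
                "pixel_size_um": self.pixel_size_um,
                "frame_rate_hz": self.frame_rate_hz,
            },
        )

    @classmethod
    def from_tiff(cls, path: str | Path,
                  pixel_size_um: float | None = None,
                  frame_rate_hz: float | None = None) -> "ImageStack":
        with tifffile.TiffFile(Path(path)) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if frames.ndim == 2:
            frames = frames[None]
        return cls(
            frames=frames,
            pixel_size_um=pixel_size_um or float(meta.get("pixel_size_um", 0.326)),
            frame_rate_hz=frame_rate_hz or float(meta.get("frame_rate_hz", 30.0)),
        )


# ---------------------------------------------------------------------------
# run-and-tumble simulator
# ---------------------------------------------------------------------------

def _draw_turn_angle(rng: np.random.Generator, sd_rad: float, min_rad: float) -> float:
    """One signed post-tumble turn, wrapped-normal(0, sd) with optional floor."""
    for _ in range(1000):
        a = rng.normal(0.0, sd_rad) if sd_rad > 0 else 0.0
        a = (a + np.pi) % (2 * np.pi) - np.pi   # wrap to (-pi, pi]
        if abs(a) >= min_rad:
            return a
    # pathological floor (e.g. min >= pi with tiny sd): fall back to the floor
    return min_rad if rng.uniform() < 0.5 else -min_rad


def _reflect(coords: np.ndarray, size: float) -> np.ndarray:
    """Fold an unbounded path into [0, size] (billiard reflection by unfolding)."""
    period = 2.0 * size
    m = np.mod(coords, period)
    return np.where(m > size, period - m, m)


def simulate_run_and_tumble(params: SimulationParams) -> TrajectorySet:
    """Simulate run-and-tumble swimmers sampled at the video frame rate.

    Returns a :class:`TrajectorySet` whose ``events`` table is the
    ground-truth tumble log (``particle``, ``frame``, ``t_s``) and whose
    ``ground_truth`` table records each cell's motility and true speed.
    """
    params.validate()
    dt = 1.0 / params.frame_rate
    n_frames = int(round(params.duration * params.frame_rate)) + 1
    n_steps = n_frames - 1
    t = np.arange(n_frames) * dt
    width, height = params.arena

    root = np.random.SeedSequence(params.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(max(params.n_cells, 1))]

    sd_rad = np.deg2rad(params.turn_angle_sd)
    min_rad = np.deg2rad(params.turn_angle_min)

    rows, event_rows, gt_rows = [], [], []
    for cell in range(params.n_cells):
        rng = streams[cell]
        # fixed draw order so parameter values never shift the stream
        start = np.array([rng.uniform(0, width), rng.uniform(0, height)])
        motile = rng.uniform() >= params.nonmotile_fraction
        speed = params.mean_speed + params.speed_sd * rng.standard_normal()
        speed = max(speed, 0.0)
        heading0 = rng.uniform(0, 2 * np.pi)

        if motile:
            # Poisson tumble times on (0, duration]
            times = []
            tk = rng.exponential(1.0 / params.tumble_rate) if params.tumble_rate > 0 else np.inf
            while tk < t[-1]:
                times.append(tk)
                tk += rng.exponential(1.0 / params.tumble_rate)
            ev_frames = np.minimum((np.asarray(times) / dt).astype(int), n_frames - 1)

            # piecewise-constant heading: each tumble's turn takes effect
            # when its slow window (tumble_duration frames) ends
            head = np.full(n_steps, heading0)
            mult = np.ones(n_steps)
            for ef in ev_frames:
                turn = _draw_turn_angle(rng, sd_rad, min_rad)
                lo = min(ef, n_steps)
                hi = min(ef + params.tumble_duration, n_steps)
                mult[lo:hi] = params.tumble_speed_fraction
                head[hi:] += turn
            steps = (speed * dt * mult)[:, None] * np.c_[np.cos(head), np.sin(head)]
            pos = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            for tk, ef in zip(times, ev_frames):
                event_rows.append((cell, int(ef), float(tk)))
        else:
            jitter = params.nonmotile_jitter_sd * rng.standard_normal((n_frames, 2))
            pos = start + jitter

        if params.boundary == "reflect":
            pos = np.c_[_reflect(pos[:, 0], width), _reflect(pos[:, 1], height)]

        pos = pos + np.asarray(params.drift_velocity) * t[:, None]
        noise = rng.standard_normal((n_frames, 2)) * params.noise_sd
        pos = pos + noise

        rows.append(pd.DataFrame({
            "particle": cell,
            "frame": np.arange(n_frames),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
        }))
        gt_rows.append((cell, bool(motile), float(speed)))

    data = (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["particle", "frame", "x_um", "y_um"]))
    events = pd.DataFrame(event_rows, columns=["particle", "frame", "t_s"])
    ground_truth = pd.DataFrame(gt_rows, columns=["particle", "motile", "speed_um_s"])
    cal = Calibration(pixel_size_um=0.326, frame_rate_hz=params.frame_rate)
    return TrajectorySet(data, cal, events=events, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# video rendering
# ---------------------------------------------------------------------------

def render_video(trajectories: TrajectorySet, imaging: ImagingParams) -> ImageStack:
    """Render a trajectory set into a 16-bit grayscale image stack.

    Each frame is ``background_pattern + background_level`` plus one
    isotropic Gaussian spot per cell position (um coordinates converted to
    pixels with ``imaging.pixel_size_um``) plus Gaussian noise.
    """
    imaging.validate()
    H, W = imaging.frame_shape
    df = trajectories.data
    frames_idx = (np.arange(int(df["frame"].max()) + 1)
                  if len(df) else np.arange(1))
    n_t = len(frames_idx)

    base = np.full((H, W), imaging.background_level, dtype=np.float64)
    if imaging.background_pattern is not None:
        base += imaging.background_pattern
    stack = np.repeat(base[None], n_t, axis=0)

    if len(df):
        x_px = df["x_um"].to_numpy() / imaging.pixel_size_um
        y_px = df["y_um"].to_numpy() / imaging.pixel_size_um
        inside = (x_px >= 0) & (x_px <= W - 1) & (y_px >= 0) & (y_px <= H - 1)
        if not inside.all():
            n_out = int((~inside).sum())
            warnings.warn(
                f"{n_out} positions fall outside the {H}x{W} field of view "
                f"({imaging.out_of_frame})", stacklevel=2)
            if imaging.out_of_frame == "clip":
                x_px = np.clip(x_px, 0, W - 1)
                y_px = np.clip(y_px, 0, H - 1)
                inside = np.ones_like(inside)

        half = max(int(np.ceil(4 * imaging.psf_sigma)), 2)
        fr = df["frame"].to_numpy()
        for i in np.flatnonzero(inside):
            xc, yc, k = x_px[i], y_px[i], fr[i]
            x0, x1 = max(int(xc) - half, 0), min(int(xc) + half + 2, W)
            y0, y1 = max(int(yc) - half, 0), min(int(yc) + half + 2, H)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            spot = imaging.spot_amplitude * np.exp(
                -((xx - xc) ** 2 + (yy - yc) ** 2) / (2 * imaging.psf_sigma ** 2))
            stack[k, y0:y1, x0:x1] += spot

    if imaging.noise_sd > 0:
        rng = np.random.default_rng(imaging.seed)
        stack = stack + rng.standard_normal(stack.shape) * imaging.noise_sd

    if not np.all(np.isfinite(stack)):
        raise ValueError("rendered intensities are not finite")
    stack = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return ImageStack(
        frames=stack,
        pixel_size_um=imaging.pixel_size_um,
        frame_rate_hz=trajectories.calibration.frame_rate_hz,
    )


# ---------------------------------------------------------------------------
# ISCA count tables
# ---------------------------------------------------------------------------

def generate_isca_counts(design: IscaDesign) -> pd.DataFrame:
    """Simulate pooled ISCA well concentrations with known treatment effects.

    Returns a table with columns ``plate``, ``treatment``, ``cells_per_ml``,
    ``is_control``; one pooled measurement per plate x treatment drawn from
    the negative-binomial count model described on :class:`IscaDesign`.
    """
    design.validate()
    treatments = design.resolved_treatments()
    root = np.random.SeedSequence(design.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(design.n_plates)]

    rows = []
    for p in range(design.n_plates):
        rng = streams[p]
        for name, effect in treatments:
            mu = design.control_mean * effect * design.sample_volume_ml
            if design.dispersion == 0:
                count = float(np.round(mu))
            elif mu == 0:
                count = 0.0
            else:
                k = 1.0 / design.dispersion
                count = float(rng.negative_binomial(k, k / (k + mu)))
            rows.append({
                "plate": p + 1,
                "treatment": name,
                "cells_per_ml": count / design.sample_volume_ml,
                "is_control": name == design.control_name,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# environmental covariate tables
# ---------------------------------------------------------------------------

def generate_environment_table(
    n_days: int,
    n_variables: int,
    linked_indices: tuple[int, ...] = (),
    target_rho: float = 0.0,
    seed: int = 0,
    ic_location: float = 2.6,
    ic_log_sd: float = 0.6,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a day x covariate table plus a chemotactic-index series.

    Variables at ``linked_indices`` are rank-correlated with the emitted
    I_C series at approximately ``target_rho`` (exactly +-1 when
    ``|target_rho| == 1``, via a monotone transform); all other variables
    are independent Gaussian noise. The I_C series is lognormal around
    ``ic_location``. Spearman-matching uses the Gaussian-copula relation
    pearson = 2 sin(pi * rho / 6).
    """
    if n_days < 4:
        raise ValueError("n_days must be >= 4 for a usable rank correlation")
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    if not (-1.0 <= target_rho <= 1.0):
        raise ValueError("|target_rho| must be <= 1")
    bad = [i for i in linked_indices if not (0 <= i < n_variables)]
    if bad:
        raise ValueError(f"linked_indices out of range: {bad}")

    rng = np.random.default_rng(seed)
    z_ic = rng.standard_normal(n_days)
    ic = ic_location * np.exp(ic_log_sd * z_ic)

    linked = set(linked_indices)
    cols = {}
    r_pearson = 2.0 * np.sin(np.pi * target_rho / 6.0)
    for j in range(n_variables):
        name = f"var_{j:02d}"
        if j in linked:
            if target_rho == 1.0:
                cols[name] = np.sqrt(ic)          # monotone in I_C: rho exactly 1
            elif target_rho == -1.0:
                cols[name] = -np.sqrt(ic)
            else:
                eps = rng.standard_normal(n_days)
                cols[name] = r_pearson * z_ic + np.sqrt(1 - r_pearson ** 2) * eps
        else:
            cols[name] = rng.standard_normal(n_days)

    days = pd.Index(range(1, n_days + 1), name="day")
    env = pd.DataFrame(cols, index=days)
    return env, pd.Series(ic, index=days, name="ic_laminarin")
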