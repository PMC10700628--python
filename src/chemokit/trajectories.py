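"""Trajectory container shared by the simulator, the tracker and the motility stage.

A :class:`TrajectorySet` is a long-format table (one row per particle per
frame) plus the calibration needed to interpret it physically, and — when it
comes from the simulator — the ground-truth tumble-event log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .calibration import Calibration

#: canonical column order of the trajectory CSV
CSV_COLUMNS = ["particle", "frame", "x", "y", "x_um", "y_um", "t_s"]


@dataclass
class TrajectorySet:
    """A set of single-cell trajectories with physical calibration.

    Attributes
    ----------
    data : pandas.DataFrame
        Long-format table with columns ``particle``, ``frame``, ``x_um``,
        ``y_um``. Frames are integer indices, strictly increasing within a
        particle.
    calibration : Calibration
        Pixel size and frame rate used for unit conversion.
    events : pandas.DataFrame or None
        Ground-truth tumble log (columns ``particle``, ``frame``, ``t_s``)
        when produced by the simulator; ``None`` for tracked data.
    ground_truth : pandas.DataFrame or None
        Per-cell simulation ground truth (``particle``, ``motile``,
        ``speed_um_s``) when available.
    """

    data: pd.DataFrame
    calibration: Calibration = field(default_factory=Calibration)
    events: pd.DataFrame | None = None
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"particle", "frame", "x_um", "y_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        self.data = self.data.sort_values(["particle", "frame"]).reset_index(drop=True)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return int(self.data["particle"].nunique())

    @property
    def particles(self) -> np.ndarray:
        return self.data["particle"].unique()

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].nunique())

    def __iter__(self) -> Iterator[tuple[int, pd.DataFrame]]:
        """Iterate (particle id, per-particle frame-sorted sub-table)."""
        for pid, group in self.data.groupby("particle", sort=True):
            yield pid, group

    def positions_um(self, particle) -> np.ndarray:
        g = self.data[self.data["particle"] == particle]
        return g[["x_um", "y_um"]].to_numpy()

    # -- unit handling -----------------------------------------------------
    def with_pixel_columns(self) -> pd.DataFrame:
        """Return the table with pixel (``x``, ``y``) and time columns added."""
        df = self.data.copy()
        df["x"] = self.calibration.um_to_px(df["x_um"])
        df["y"] = self.calibration.um_to_px(df["y_um"])
        df["t_s"] = self.calibration.frame_to_s(df["frame"])
        return df

    # -- persistence -------------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: str | Path | None = None, **meta) -> None:
        """Write ``particle, frame, x, y, x_um, y_um, t_s`` CSV plus a JSON sidecar.

        ``x``/``y`` are pixels under the stored calibration; the sidecar
        records ``pixel_size_um`` and ``frame_rate_hz`` (plus any ``meta``).
        """
        path = Path(path)
        df = self.with_pixel_columns()
        df[CSV_COLUMNS].to_csv(path, index=False)
        if sidecar is None:
            sidecar = path.with_suffix(".json")
        self.calibration.to_json(sidecar, **meta)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        calibration: Calibration | None = None,
        sidecar: str | Path | None = None,
    ) -> "TrajectorySet":
        """Read a trajectory CSV; physical columns are rebuilt if absent.

        A calibration may be given directly or found in the JSON sidecar
        next to the CSV. A bare ``particle, frame, x, y`` table (pixels) is
        accepted and converted to micrometres.
        """
        path = Path(path)
        df = pd.read_csv(path)
        if calibration is None:
            if sidecar is None:
                sidecar = path.with_suffix(".json")
            if Path(sidecar).exists():
                calibration = Calibration.from_json(sidecar)
            else:
                raise ValueError(
                    f"no calibration given and no sidecar found at {sidecar}"
                )
        if "x_um" not in df.columns:
            df["x_um"] = calibration.px_to_um(df["x"])
            df["y_um"] = calibration.px_to_um(df["y"])
        return cls(df[["particle", "frame", "x_um", "y_um"]], calibration)

    # -- editing -----------------------------------------------------------
    def filter_particles(self, keep) -> "TrajectorySet":
        mask = self.data["particle"].isin(np.asarray(list(keep)))
        events = None
        if self.events is not None:
            events = self.events[self.events["particle"].isin(np.asarray(list(keep)))]
            events = events.reset_index(drop=True)
        gt = None
        if self.ground_truth is not None:
            gt = self.ground_truth[self.ground_truth["particle"].isin(np.asarray(list(keep)))]
            gt = gt.reset_index(drop=True)
        return TrajectorySet(
            self.data[mask].reset_index(drop=True), self.calibration, events, gt
        )
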