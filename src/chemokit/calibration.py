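"""Physical calibration shared by every stage of the pipeline.

All unit conversions (pixels <-> micrometres, frames <-> seconds) go through a
single :class:`Calibration` object so that no stage can apply a scale twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path


@dataclass(frozen=True)
class Calibration:
    """Microscope calibration: spatial scale and acquisition rate.

    Parameters
    ----------
    pixel_size_um : float
        Physical size of one camera pixel, in micrometres (default 0.326,
        a 20x phase-contrast setup on a 2044 x 2048 CMOS sensor).
    frame_rate_hz : float
        Acquisition speed in frames per second (typically 25-30 for
        swimming marine bacteria).
    """

    pixel_size_um: float = 0.326
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.frame_rate_hz > 0):
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate_hz

    def px_to_um(self, px):
        return px * self.pixel_size_um

    def um_to_px(self, um):
        return um / self.pixel_size_um

    def frame_to_s(self, frame):
        return frame / self.frame_rate_hz

    def to_json(self, path: str | Path, **extra) -> None:
        """Write a sidecar JSON with the calibration plus free-form metadata."""
        payload = {**asdict(self), **extra}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        payload = json.loads(Path(path).read_text())
        return cls(
            pixel_size_um=payload["pixel_size_um"],
            frame_rate_hz=payload["frame_rate_hz"],
        )
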