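"""Frame storage: in-memory video container with an on-disk directory layout.

A :class:`FrameStore` holds 8-bit grayscale frames together with a per-frame
index of ``(frame_number, timestamp_s)`` pairs and acquisition metadata
(frame rate, spatial calibration, camera id, photostimulation schedule).
Timekeeping downstream always goes through the timestamps, never through
frame counts, so dropped or skipped frames do not cause temporal drift.

On disk a store is a directory::

    store/
      frame_000000.png ...   8-bit grayscale PNG, one per frame
      index.csv              columns: frame_number, timestamp_s
      metadata.yaml          frame_rate, px_per_mm, camera_id, schedule
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .schedule import StimulusSchedule


@dataclass
class FrameStore:
    frames: np.ndarray  # (T, H, W) uint8
    index: pd.DataFrame  # columns frame_number (int), timestamp_s (float)
    frame_rate: float
    px_per_mm: float = 80.6
    camera_id: int = 1
    schedule: StimulusSchedule | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be uint8")
        if len(self.index) != len(self.frames):
            raise ValueError("index length must match frame count")
        fn = self.index["frame_number"].to_numpy()
        ts = self.index["timestamp_s"].to_numpy()
        if not (np.all(np.diff(fn) > 0) and np.all(np.diff(ts) > 0)):
            raise ValueError("index must be strictly increasing in frame_number and timestamp")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        return self.index["timestamp_s"].to_numpy(dtype=float)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
        self.index.to_csv(path / "index.csv", index=False)
        meta = {
            "frame_rate": float(self.frame_rate),
            "px_per_mm": float(self.px_per_mm),
            "camera_id": int(self.camera_id),
            "schedule": self.schedule.to_dict() if self.schedule else None,
            **self.extra,
        }
        with open(path / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FrameStore":
        path = Path(path)
        index = pd.read_csv(path / "index.csv")
        files = sorted(path.glob("frame_*.png"))
        if len(files) != len(index):
            raise ValueError("frame files do not match index.csv")
        frames = np.stack([iio.imread(f) for f in files])
        with open(path / "metadata.yaml") as fh:
            meta = yaml.safe_load(fh)
        sched = meta.pop("schedule", None)
        return cls(
            frames=frames.astype(np.uint8),
            index=index,
            frame_rate=float(meta.pop("frame_rate")),
            px_per_mm=float(meta.pop("px_per_mm", 80.6)),
            camera_id=int(meta.pop("camera_id", 1)),
            schedule=StimulusSchedule.from_dict(sched) if sched else None,
            extra=meta,
        )
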