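"""Time-series image stacks: in-memory container and TIFF + sidecar IO.

Stacks are stored as multi-page TIFF (16-bit unsigned) with a plain-text
``key = value`` sidecar carrying the physical calibration (``pixel_size_um``,
``frame_interval_s``), mirroring how microscope acquisitions typically travel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .tracks import read_keyvalue, write_keyvalue


@dataclass
class ImageStack:
    """Uniformly sampled intensity movie.

    frames : (time, row, col) array; pixel (0, 0) is the top-left corner.
    pixel_size : um per pixel.  frame_interval : seconds between frames.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack needs >= 2 frames with shape (time, row, col)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if not np.isfinite(np.asarray(self.frames, dtype=float)).all():
            raise ValueError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".meta.txt")


def save_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a 16-bit multi-page TIFF plus its calibration sidecar."""
    path = Path(path)
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    write_keyvalue(
        {"pixel_size_um": stack.pixel_size, "frame_interval_s": stack.frame_interval},
        sidecar_path(path),
    )
    return path


def load_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Load a TIFF stack; calibration from arguments or the sidecar file."""
    path = Path(path)
    frames = tifffile.imread(path)
    if pixel_size is None or frame_interval is None:
        side = sidecar_path(path)
        if not side.exists():
            raise ValueError(
                f"{path}: pixel_size/frame_interval not given and no sidecar {side.name}"
            )
        meta = read_keyvalue(side)
        if pixel_size is None:
            pixel_size = float(meta["pixel_size_um"])
        if frame_interval is None:
            frame_interval = float(meta["frame_interval_s"])
    return ImageStack(frames=frames, pixel_size=pixel_size, frame_interval=frame_interval)
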