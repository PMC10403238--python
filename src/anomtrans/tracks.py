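"""Particle trajectory tables and their on-disk CSV dialect.

Trajectories live in a :class:`TrackTable`: a tidy table of
``(particle, frame, x, y)`` records with positions in micrometres plus the
acquisition calibration (``frame_interval`` in seconds, ``pixel_size`` in
micrometres per pixel).  On disk the table uses the dialect emitted by common
tracking software: a CSV with header ``frame,particle,x,y`` where positions
are in *pixels* and frame indices are 0-based.  Conversion to physical units
happens at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("frame", "particle", "x", "y")


@dataclass
class TrackTable:
    """Calibrated per-particle position time series.

    Parameters
    ----------
    data
        DataFrame with columns ``particle`` (id), ``frame`` (0-based index),
        ``x``, ``y`` (micrometres), sorted by particle then frame.
    frame_interval
        Time between consecutive frames, seconds.
    pixel_size
        Camera calibration, micrometres per pixel (already applied to x/y).
    source
        Free-text label for provenance.
    meta
        Generator ground truth or loader bookkeeping (e.g. exclusion counts).
    """

    data: pd.DataFrame
    frame_interval: float
    pixel_size: float = 1.0
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        missing = [c for c in ("particle", "frame", "x", "y") if c not in self.data.columns]
        if missing:
            raise ValueError(f"TrackTable missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("TrackTable is empty")
        if not np.isfinite(self.data[["x", "y"]].to_numpy()).all():
            raise ValueError("positions must be finite")

    @property
    def n_particles(self) -> int:
        return self.data["particle"].nunique()

    def positions(self) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-particle ``(frames, x, y)`` arrays, frames strictly increasing."""
        out = {}
        for pid, grp in self.data.groupby("particle", sort=True):
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"frames not strictly increasing for particle {pid}")
            out[pid] = (frames, grp["x"].to_numpy(float), grp["y"].to_numpy(float))
        return out

    def displacements(self, lag_steps: int) -> tuple[np.ndarray, np.ndarray]:
        """Pooled per-axis displacements at an integer lag (all pairs, all particles)."""
        if lag_steps < 1:
            raise ValueError("lag_steps must be >= 1")
        dxs, dys = [], []
        for frames, x, y in self.positions().values():
            if len(frames) <= lag_steps:
                continue
            if _is_contiguous(frames):
                dxs.append(x[lag_steps:] - x[:-lag_steps])
                dys.append(y[lag_steps:] - y[:-lag_steps])
            else:
                xf, yf = _dense_positions(frames, x, y)
                dx = xf[lag_steps:] - xf[:-lag_steps]
                dy = yf[lag_steps:] - yf[:-lag_steps]
                keep = np.isfinite(dx)
                dxs.append(dx[keep])
                dys.append(dy[keep])
        if not dxs:
            return np.empty(0), np.empty(0)
        return np.concatenate(dxs), np.concatenate(dys)


def _is_contiguous(frames: np.ndarray) -> bool:
    return bool(np.all(np.diff(frames) == 1))


def _dense_positions(frames: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Positions on a dense frame grid with NaN at unobserved frames."""
    span = frames[-1] - frames[0] + 1
    xf = np.full(span, np.nan)
    yf = np.full(span, np.nan)
    idx = frames - frames[0]
    xf[idx] = x
    yf[idx] = y
    return xf, yf


def read_tracks(
    path: str | Path,
    pixel_size: float,
    frame_interval: float,
    min_track_length: int = 10,
) -> TrackTable:
    """Load a ``frame,particle,x,y`` CSV (pixel units) into a calibrated table.

    Positions are converted to micrometres via ``pixel_size``; particles
    observed in fewer than ``min_track_length`` frames are dropped (count
    recorded in ``meta['n_excluded_short']`` and logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty track file") from err
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no track records")
    for col in REQUIRED_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    df = df.sort_values(["particle", "frame"], kind="stable").reset_index(drop=True)
    counts = df.groupby("particle")["frame"].size()
    keep = counts[counts >= min_track_length].index
    n_excluded = int(counts.size - keep.size)
    if n_excluded:
        logger.info("read_tracks: excluded %d tracks shorter than %d frames",
                    n_excluded, min_track_length)
    df = df[df["particle"].isin(keep)].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"{path}: all tracks shorter than min_track_length={min_track_length}")
    df["x"] = df["x"] * pixel_size
    df["y"] = df["y"] * pixel_size
    return TrackTable(
        data=df[["particle", "frame", "x", "y"]],
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        source=str(path),
        meta={"n_excluded_short": n_excluded, "min_track_length": min_track_length},
    )


def write_tracks(table: TrackTable, path: str | Path) -> Path:
    """Write the ``frame,particle,x,y`` CSV dialect (positions back in pixels)."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "frame": table.data["frame"].astype(int),
            "particle": table.data["particle"].astype(int),
            "x": table.data["x"] / table.pixel_size,
            "y": table.data["y"] / table.pixel_size,
        }
    )
    out.to_csv(path, index=False)
    return path


def write_keyvalue(mapping: Mapping, path: str | Path) -> Path:
    """Plain ``key = value`` sidecar used for calibration and ground truth."""
    path = Path(path)
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_keyvalue(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out
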