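"""Domain containers and file I/O for cortical-flow analysis.

Coordinate convention: continuous micrometres, origin at the image's
top-left corner, x increasing toward the posterior pole, y orthogonal to
the anterior-posterior (AP) axis.  The centre of pixel (row, col) sits at
``x = (col + 0.5) * pixel_size`` and ``y = (row + 0.5) * pixel_size``
(0-based indices).  Velocities are micrometres per minute throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Frame",
    "Movie",
    "VelocityField",
    "read_movie",
    "write_movie",
    "read_velocity_fields",
    "write_velocity_fields",
    "max_project",
]

VELOCITY_COLUMNS = ("frame", "x_um", "y_um", "vx", "vy")


@dataclass
class Frame:
    """A single cortical image plane.

    Parameters
    ----------
    intensity
        2D non-negative array of fluorescence intensities (arbitrary units).
    pixel_size
        Edge length of one pixel in micrometres.
    time
        Acquisition time in seconds since the start of the movie.
    """

    intensity: np.ndarray
    pixel_size: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2 or min(self.intensity.shape) < 2:
            raise ValueError("intensity must be a 2D grid of at least 2x2 pixels")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the frame in micrometres."""
        h, w = self.intensity.shape
        return w * self.pixel_size, h * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x (per column) and y (per row) pixel-centre coordinates in um."""
        h, w = self.intensity.shape
        x = (np.arange(w) + 0.5) * self.pixel_size
        y = (np.arange(h) + 0.5) * self.pixel_size
        return x, y


@dataclass
class Movie:
    """Ordered sequence of co-registered frames at a uniform interval."""

    frames: list[Frame]
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("movie must contain at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        first = self.frames[0]
        for fr in self.frames:
            if fr.shape != first.shape:
                raise ValueError("all frames must share one shape")
            if fr.pixel_size != first.pixel_size:
                raise ValueError("all frames must share one pixel size")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    @property
    def duration(self) -> float:
        return (len(self.frames) - 1) * self.frame_interval


@dataclass
class VelocityField:
    """PIV-style velocity field on a regular grid of nodes.

    Nodes are stored flat; ``x``/``y`` are node-centre positions in um and
    ``vx``/``vy`` velocity components in um/min.  Missing vectors are NaN.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        n = self.x.size
        if not (self.y.size == self.vx.size == self.vy.size == n):
            raise ValueError("x, y, vx, vy must have equal length")
        if n == 0:
            raise ValueError("velocity field has no nodes")

    @property
    def n_nodes(self) -> int:
        return self.x.size

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.vx) & np.isfinite(self.vy)


def read_movie(path: str | Path, pixel_size: float, frame_interval: float = 5.0) -> Movie:
    """Read a multi-page grayscale TIFF as a :class:`Movie`.

    Frame times are ``page_index * frame_interval`` seconds.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    stack = tifffile.imread(str(path))
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
    frames = [
        Frame(plane, pixel_size=pixel_size, time=i * frame_interval)
        for i, plane in enumerate(stack)
    ]
    return Movie(frames, frame_interval=frame_interval)


def write_movie(path: str | Path, movie: Movie, dtype: str = "float32") -> None:
    """Write a movie as a multi-page TIFF with the given sample dtype."""
    stack = np.stack([fr.intensity for fr in movie.frames]).astype(dtype)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def max_project(planes: Sequence[Frame] | Sequence[np.ndarray]) -> Frame:
    """Per-pixel maximum-intensity projection of co-registered planes."""
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    if isinstance(planes[0], Frame):
        arrays = [p.intensity for p in planes]
        pixel_size = planes[0].pixel_size
        time = planes[0].time
    else:
        arrays = [np.asarray(p, dtype=float) for p in planes]
        pixel_size = 1.0
        time = 0.0
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("planes must share one shape")
    return Frame(np.maximum.reduce(arrays), pixel_size=pixel_size, time=time)


def read_velocity_fields(
    path: str | Path, unit_scale: float = 1.0
) -> list[VelocityField]:
    """Read per-frame velocity fields from a delimited text table.

    The table must carry columns ``frame, x_um, y_um, vx, vy`` (comma or
    tab separated).  ``unit_scale`` multiplies vx/vy, converting whatever
    unit the file uses into um/min (e.g. 60 for um/s input).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in VELOCITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"velocity table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("no records in velocity table")
    fields = []
    for frame_idx, sub in df.groupby("frame", sort=True):
        sub = sub.sort_values(["y_um", "x_um"], kind="mergesort")
        _check_regular_grid(sub["x_um"].to_numpy(), sub["y_um"].to_numpy())
        fields.append(
            VelocityField(
                x=sub["x_um"].to_numpy(),
                y=sub["y_um"].to_numpy(),
                vx=sub["vx"].to_numpy() * unit_scale,
                vy=sub["vy"].to_numpy() * unit_scale,
                frame_index=int(frame_idx),
            )
        )
    return fields


def _check_regular_grid(x: np.ndarray, y: np.ndarray) -> None:
    nodes = set(zip(x.tolist(), y.tolist()))
    if len(nodes) != x.size:
        raise ValueError("irregular grid: duplicated nodes")
    ux, uy = np.unique(x), np.unique(y)
    if ux.size * uy.size != x.size:
        raise ValueError("irregular grid: nodes do not form a complete lattice")


def write_velocity_fields(path: str | Path, fields: Iterable[VelocityField]) -> None:
    """Write velocity fields to CSV in the canonical column layout."""
    parts = []
    for f in fields:
        parts.append(
            pd.DataFrame(
                {
                    "frame": f.frame_index,
                    "x_um": f.x,
                    "y_um": f.y,
                    "vx": f.vx,
                    "vy": f.vy,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
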