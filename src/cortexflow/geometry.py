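"""Embryo geometry, AP-axis binning, and binned intensity/velocity profiles.

The embryo's long (anterior-posterior) axis is divided into ``n_bins``
equal bins, anterior at ``x_min``.  Bin indices are 1-based.  Spatial
averaging of velocities and intensity is restricted to a horizontal
stripe of configurable height centred on the embryo midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import Frame, VelocityField

__all__ = ["EmbryoGeometry", "AnalysisWindow", "BinnedProfile", "bin_profile"]


@dataclass(frozen=True)
class EmbryoGeometry:
    """Binning layout along the AP axis plus the analysis sub-regions.

    Parameters
    ----------
    ap_extent
        (x_min, x_max) in um, anterior pole at x_min.
    y_mid
        y coordinate of the embryo midline in um; if None it is taken as
        the midpoint of the data's y range when a stripe is applied.
    n_bins
        Number of equal AP bins (default 18).
    stripe_height
        Height in um of the midline stripe used for spatial averages.
    posterior_bins, anterior_bins
        1-based bin indices of the posterior and anterior averaging
        regions (defaults 13-16 and 3-6).
    foci_stripe_width
        Width in um of the anterior stripe used for foci analysis,
        centred on the boundary between bins 7 and 8.
    oscillation_box
        Edge length in um of the square posterior box (centred on the
        boundary between bins 14 and 15) used for the pulsation series.
    """

    ap_extent: tuple[float, float]
    y_mid: Optional[float] = None
    n_bins: int = 18
    stripe_height: float = 13.0
    posterior_bins: tuple[int, ...] = (13, 14, 15, 16)
    anterior_bins: tuple[int, ...] = (3, 4, 5, 6)
    foci_stripe_width: float = 27.0
    oscillation_box: float = 6.0

    def __post_init__(self) -> None:
        x_min, x_max = self.ap_extent
        if not x_max > x_min:
            raise ValueError("ap_extent must satisfy x_min < x_max")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        for idx in (*self.posterior_bins, *self.anterior_bins):
            if not 1 <= idx <= self.n_bins:
                raise ValueError("bin indices are 1-based and must be <= n_bins")
        if set(self.posterior_bins) & set(self.anterior_bins):
            raise ValueError("posterior and anterior bin sets must be disjoint")
        if self.stripe_height <= 0:
            raise ValueError("stripe_height must be positive")

    @property
    def bin_width(self) -> float:
        x_min, x_max = self.ap_extent
        return (x_max - x_min) / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        x_min, x_max = self.ap_extent
        return np.linspace(x_min, x_max, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def bin_of(self, x: np.ndarray) -> np.ndarray:
        """0-based bin index per coordinate; -1 outside the AP extent.

        Bins are half-open [left, right); the last bin is closed.
        """
        x = np.asarray(x, dtype=float)
        x_min, x_max = self.ap_extent
        idx = np.floor((x - x_min) / self.bin_width).astype(int)
        idx[np.isclose(x, x_max)] = self.n_bins - 1
        idx[(x < x_min) | (x > x_max)] = -1
        idx[idx >= self.n_bins] = -1
        return idx

    def boundary_x(self, k: int) -> float:
        """x position of the boundary between 1-based bins k and k+1."""
        return self.ap_extent[0] + k * self.bin_width

    @property
    def foci_stripe_center_x(self) -> float:
        return self.boundary_x(7)

    @property
    def oscillation_box_center_x(self) -> float:
        return self.boundary_x(14)

    def resolve_y_mid(self, y: np.ndarray) -> float:
        if self.y_mid is not None:
            return self.y_mid
        y = np.asarray(y, dtype=float)
        return 0.5 * (float(np.min(y)) + float(np.max(y)))

    def stripe_mask(self, y: np.ndarray, y_mid: Optional[float] = None) -> np.ndarray:
        """Boolean mask of coordinates inside the midline stripe (closed)."""
        if y_mid is None:
            y_mid = self.resolve_y_mid(y)
        return np.abs(np.asarray(y, dtype=float) - y_mid) <= self.stripe_height / 2.0


@dataclass(frozen=True)
class AnalysisWindow:
    """Frame window of the flow period; foci analysis uses the first 75 s."""

    start_frame: int
    end_frame: int
    foci_duration: float = 75.0

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must be < end_frame")
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")

    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)

    def foci_frames(self, frame_interval: float) -> range:
        n = int(np.floor(self.foci_duration / frame_interval))
        return range(self.start_frame, min(self.start_frame + n + 1, self.end_frame + 1))


@dataclass
class BinnedProfile:
    """Per-AP-bin averages of intensity and velocity with standard errors.

    Bins with no in-stripe samples are flagged missing (NaN values,
    ``missing`` True) and must be excluded from downstream averages.
    """

    bin_centers: np.ndarray
    I: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    sem_I: np.ndarray
    sem_vx: np.ndarray
    sem_vy: np.ndarray
    n_samples: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        n = self.bin_centers.size
        for name in ("I", "vx", "vy", "sem_I", "sem_vx", "sem_vy", "n_samples"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if self.missing is None:
            self.missing = self.n_samples == 0
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.nan, np.nan
    mean = float(np.mean(values))
    if values.size < 2:
        return mean, np.nan
    return mean, float(np.std(values, ddof=1) / np.sqrt(values.size))


def bin_profile(
    field: VelocityField,
    frame: Optional[Frame],
    geom: EmbryoGeometry,
) -> BinnedProfile:
    """Project a velocity field (and optionally an image) onto AP bins.

    Velocities are averaged per bin over nodes inside the bin x midline
    stripe; intensity is averaged over pixel centres inside the same
    region.  Bins with zero velocity samples are flagged missing.
    """
    y_mid = geom.resolve_y_mid(field.y)
    in_stripe = geom.stripe_mask(field.y, y_mid)
    bins = geom.bin_of(field.x)
    valid = in_stripe & (bins >= 0) & field.valid_mask()
    if not np.any(in_stripe & (bins >= 0)):
        raise ValueError("geometry does not overlap the velocity-field extent")

    nb = geom.n_bins
    vx = np.full(nb, np.nan)
    vy = np.full(nb, np.nan)
    sem_vx = np.full(nb, np.nan)
    sem_vy = np.full(nb, np.nan)
    n_samples = np.zeros(nb)
    for b in range(nb):
        sel = valid & (bins == b)
        n_samples[b] = int(np.sum(sel))
        if n_samples[b] > 0:
            vx[b], sem_vx[b] = _mean_sem(field.vx[sel])
            vy[b], sem_vy[b] = _mean_sem(field.vy[sel])

    I = np.full(nb, np.nan)
    sem_I = np.full(nb, np.nan)
    if frame is not None:
        px, py = frame.pixel_centers()
        y_mid_img = geom.y_mid if geom.y_mid is not None else 0.5 * (py[0] + py[-1])
        row_mask = geom.stripe_mask(py, y_mid_img)
        col_bins = geom.bin_of(px)
        for b in range(nb):
            cols = col_bins == b
            if np.any(cols) and np.any(row_mask):
                patch = frame.intensity[np.ix_(row_mask, cols)]
                I[b] = float(np.mean(patch))
                sem_I[b] = float(np.std(patch, ddof=1) / np.sqrt(patch.size)) if patch.size > 1 else np.nan

    return BinnedProfile(
        bin_centers=geom.bin_centers,
        I=I,
        vx=vx,
        vy=vy,
        sem_I=sem_I,
        sem_vx=sem_vx,
        sem_vy=sem_vy,
        n_samples=n_samples,
    )
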