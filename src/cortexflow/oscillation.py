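"""Pulsatile-flow period estimation by temporal autocorrelation.

Cortical flow in the posterior pulses: the AP velocity averaged over a
small box (6x6 um, centred between bins 14 and 15) rises and falls with
a characteristic period of tens of seconds.  The period T_osc is read
off as the lag of the first local maximum of the normalized
autocorrelation of the mean-subtracted box-velocity series, computed up
to half the total analysis time.  Series without a peak (or without
variance) are discarded from the condition mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .flow import wilcoxon_compare
from .geometry import EmbryoGeometry
from .io import VelocityField

__all__ = [
    "VelocitySeries",
    "AutocorrResult",
    "box_velocity_series",
    "autocorrelation",
    "oscillation_period",
    "condition_period",
]

logger = logging.getLogger(__name__)


@dataclass
class VelocitySeries:
    """Uniformly sampled box-averaged AP velocity (um/min)."""

    t: np.ndarray
    v: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")
        if self.t.size < 4:
            raise ValueError("series must have at least 4 samples")
        if self.dt <= 0 or not np.allclose(np.diff(self.t), self.dt, rtol=1e-6):
            raise ValueError("sampling must be uniform with positive dt")


@dataclass
class AutocorrResult:
    """Normalized autocorrelation A(k) for lags k = 0 .. floor(T/2)."""

    lags: np.ndarray         # sample increments
    lag_seconds: np.ndarray
    A: np.ndarray
    dt: float
    no_signal: bool = False


def box_velocity_series(
    fields: list[VelocityField], geom: EmbryoGeometry, frame_interval: float
) -> VelocitySeries:
    """Mean vx over nodes inside the posterior oscillation box, per frame.

    Node centres falling in the closed box belong to it.
    """
    cx = geom.oscillation_box_center_x
    half = geom.oscillation_box / 2.0
    values = []
    for f in fields:
        cy = geom.resolve_y_mid(f.y)
        inside = (
            (np.abs(f.x - cx) <= half)
            & (np.abs(f.y - cy) <= half)
            & f.valid_mask()
        )
        if not np.any(inside):
            raise ValueError("oscillation box contains no velocity nodes")
        values.append(float(np.mean(f.vx[inside])))
    t = np.arange(len(values)) * frame_interval
    return VelocitySeries(t=t, v=np.array(values), dt=frame_interval)


def autocorrelation(series: VelocitySeries) -> AutocorrResult:
    """Biased normalized autocorrelation of the mean-subtracted series.

    A(k) = sum_t dv(t) dv(t+k), normalized so A(0) = 1, for lags up to
    half the series length.  A zero-variance series is flagged as having
    no signal (the embryo is discarded downstream).
    """
    dv = series.v - np.mean(series.v)
    denom = float(np.dot(dv, dv))
    n = dv.size
    kmax = n // 2
    lags = np.arange(kmax + 1)
    # variance at the float rounding floor counts as no signal
    floor = (1e-10 * max(1.0, float(np.max(np.abs(series.v))))) ** 2 * n
    if denom <= floor:
        return AutocorrResult(
            lags=lags,
            lag_seconds=lags * series.dt,
            A=np.full(kmax + 1, np.nan),
            dt=series.dt,
            no_signal=True,
        )
    A = np.array([float(np.dot(dv[: n - k], dv[k:])) / denom for k in lags])
    return AutocorrResult(lags=lags, lag_seconds=lags * series.dt, A=A, dt=series.dt)


def oscillation_period(acf: AutocorrResult) -> Optional[float]:
    """Lag (in seconds) of the first local maximum of A(k), k > 0.

    A peak is a strict local maximum over one-lag neighbours; a plateau
    peak is assigned the smallest lag of the plateau.  Returns None when
    no peak exists (a valid outcome: the record is discarded).
    """
    if acf.no_signal:
        return None
    A = acf.A
    kmax = A.size - 1
    k = 1
    while k < kmax:
        if A[k] > A[k - 1]:
            j = k
            while j + 1 <= kmax and A[j + 1] == A[k]:
                j += 1
            if j < kmax and A[j + 1] < A[k]:
                return float(acf.lag_seconds[k])
            k = j + 1
        else:
            k += 1
    return None


@dataclass
class ConditionPeriod:
    """Across-embryo summary of the oscillation period for one condition."""

    periods: np.ndarray
    n_discarded: int
    mean: float
    sem: float
    p_vs_control: Optional[float] = None
    significant: Optional[bool] = None


def condition_period(
    per_embryo_periods: list[Optional[float]],
    control_periods: Optional[list[float]] = None,
    confidence: float = 0.95,
) -> ConditionPeriod:
    """Mean +/- SEM of T_osc across embryos; optional rank-sum vs control.

    Embryos whose autocorrelation had no peak are excluded (counted as
    discarded).  The condition mean is over embryos, not frames.
    """
    kept = np.array([p for p in per_embryo_periods if p is not None], dtype=float)
    n_discarded = len(per_embryo_periods) - kept.size
    if n_discarded:
        logger.info("discarded %d embryo(s) without an autocorrelation peak", n_discarded)
    if kept.size == 0:
        raise ValueError("all embryos discarded: no oscillation periods")
    mean = float(np.mean(kept))
    sem = float(np.std(kept, ddof=1) / np.sqrt(kept.size)) if kept.size > 1 else 0.0
    p = sig = None
    if control_periods is not None and len(control_periods) > 0:
        p, sig = wilcoxon_compare(kept, np.asarray(control_periods), confidence=confidence)
    return ConditionPeriod(
        periods=kept, n_discarded=n_discarded, mean=mean, sem=sem,
        p_vs_control=p, significant=sig,
    )
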