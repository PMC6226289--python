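"""Per-frame and per-embryo cortical-flow statistics and comparisons.

The anterior-directed flow is summarized per frame by the mean AP
velocity over the posterior bins (13-16 by default); the chiral
counter-rotation velocity is the posterior-minus-anterior difference of
the mean y-velocity (bins 13-16 minus bins 3-6).  Per-frame values are
pooled across all embryos of a condition for histograms and means, and
conditions are compared with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import BinnedProfile, EmbryoGeometry

__all__ = [
    "FlowSummary",
    "mean_ap_velocity",
    "chiral_counter_velocity",
    "condition_histogram",
    "wilcoxon_compare",
    "time_averaged_profile",
    "correlation_report",
]

logger = logging.getLogger(__name__)

# Exact permutation enumeration is used when the number of group
# assignments is at most this; beyond it the normal approximation with
# midrank tie correction takes over.
_EXACT_ENUMERATION_CAP = 200_000


@dataclass
class FlowSummary:
    """Per-frame flow statistics for one embryo."""

    condition: str
    embryo: str
    vx_frames: np.ndarray  # per-frame posterior mean AP velocity, um/min
    vc_frames: np.ndarray  # per-frame chiral counter-rotation velocity, um/min

    def __post_init__(self) -> None:
        self.vx_frames = np.asarray(self.vx_frames, dtype=float)
        self.vc_frames = np.asarray(self.vc_frames, dtype=float)

    @property
    def vx_mean(self) -> float:
        v = self.vx_frames[np.isfinite(self.vx_frames)]
        return float(np.mean(v)) if v.size else np.nan

    @property
    def vc_mean(self) -> float:
        v = self.vc_frames[np.isfinite(self.vc_frames)]
        return float(np.mean(v)) if v.size else np.nan


def _bin_set_mean(values: np.ndarray, missing: np.ndarray, bins_1based: tuple[int, ...]) -> float:
    idx = np.array(bins_1based) - 1
    if np.all(missing[idx]):
        return np.nan
    sel = idx[~missing[idx]]
    return float(np.mean(values[sel]))


def mean_ap_velocity(profile: BinnedProfile, geom: EmbryoGeometry) -> float:
    """Posterior mean AP velocity of one frame (NaN if all bins missing)."""
    v = _bin_set_mean(profile.vx, profile.missing, geom.posterior_bins)
    if np.isnan(v):
        logger.warning("all posterior bins missing; frame skipped")
    return v


def chiral_counter_velocity(profile: BinnedProfile, geom: EmbryoGeometry) -> float:
    """Posterior-minus-anterior mean y-velocity of one frame."""
    post = _bin_set_mean(profile.vy, profile.missing, geom.posterior_bins)
    ant = _bin_set_mean(profile.vy, profile.missing, geom.anterior_bins)
    if np.isnan(post) or np.isnan(ant):
        logger.warning("posterior or anterior bin set missing; frame skipped")
        return np.nan
    return post - ant


@dataclass
class ConditionHistogram:
    """Pooled per-frame values of one condition with mean and SEM."""

    pooled: np.ndarray
    mean: float
    sem: float
    counts: np.ndarray
    edges: np.ndarray


def condition_histogram(
    summaries: list[FlowSummary], quantity: str = "vx", n_bins: int = 20
) -> ConditionHistogram:
    """Pool per-frame values across embryos of one condition.

    The condition mean and SEM are computed over the pooled per-frame
    values (mirroring per-frame pooling across the entire flow period).
    """
    if not summaries:
        raise ValueError("no embryos in condition")
    attr = {"vx": "vx_frames", "vc": "vc_frames"}[quantity]
    pooled = np.concatenate([getattr(s, attr) for s in summaries])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("empty pool of per-frame values")
    mean = float(np.mean(pooled))
    sem = float(np.std(pooled, ddof=1) / np.sqrt(pooled.size)) if pooled.size > 1 else 0.0
    counts, edges = np.histogram(pooled, bins=n_bins)
    return ConditionHistogram(pooled=pooled, mean=mean, sem=sem, counts=counts, edges=edges)


def _ranksum_exact_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact permutation p for the rank-sum statistic.

    Enumerates every assignment of n_a pooled observations to group a and
    counts assignments whose rank sum deviates from its permutation mean
    at least as much as the observed one.
    """
    n = ranks.size
    mu = n_a * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= d_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def wilcoxon_compare(
    sample_a: np.ndarray, sample_b: np.ndarray, confidence: float = 0.99
) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum test with midrank tie handling.

    Small problems are tested by exact permutation enumeration; larger
    ones by the normal approximation with tie-corrected variance and
    continuity correction.  Returns (p, significant at the confidence).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n_a].sum())

    if math.comb(n_a + n_b, n_a) <= _EXACT_ENUMERATION_CAP:
        p = _ranksum_exact_p(ranks, n_a, w_obs)
    else:
        n = n_a + n_b
        mu = n_a * (n + 1) / 2.0
        # midrank tie correction of the variance
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
        var = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)  # continuity correction
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return p, p < (1.0 - confidence)


def time_averaged_profile(
    per_embryo_profiles: list[list[BinnedProfile]],
) -> BinnedProfile:
    """Two-stage average: over frames within each embryo, then across embryos.

    SEMs are computed across embryos (NaN for a single embryo).  Missing
    bins are excluded from both averaging stages, never zero-filled.
    """
    if not per_embryo_profiles:
        raise ValueError("need at least one embryo")
    centers = per_embryo_profiles[0][0].bin_centers
    for frames in per_embryo_profiles:
        for p in frames:
            if not np.allclose(p.bin_centers, centers):
                raise ValueError("geometry mismatch between profiles")

    def embryo_mean(frames: list[BinnedProfile], attr: str) -> np.ndarray:
        stack = np.stack([getattr(p, attr) for p in frames])
        with np.errstate(invalid="ignore"):
            return np.nanmean(stack, axis=0)

    per_embryo = {
        attr: np.stack([embryo_mean(frames, attr) for frames in per_embryo_profiles])
        for attr in ("I", "vx", "vy")
    }
    n_embryos = len(per_embryo_profiles)
    out = {}
    sems = {}
    for attr, stack in per_embryo.items():
        with np.errstate(invalid="ignore"):
            counts = np.sum(np.isfinite(stack), axis=0)
            mean = np.where(counts > 0, np.nanmean(stack, axis=0), np.nan)
            if n_embryos > 1:
                sem = np.where(
                    counts > 1,
                    np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(counts, 1)),
                    np.nan,
                )
            else:
                sem = np.full(centers.size, np.nan)
        out[attr] = mean
        sems[attr] = sem
    n_samples = np.sum(
        np.stack(
            [
                np.sum(np.stack([p.n_samples for p in frames]), axis=0)
                for frames in per_embryo_profiles
            ]
        ),
        axis=0,
    )
    return BinnedProfile(
        bin_centers=centers,
        I=out["I"],
        vx=out["vx"],
        vy=out["vy"],
        sem_I=sems["I"],
        sem_vx=sems["vx"],
        sem_vy=sems["vy"],
        n_samples=n_samples,
    )


DEFAULT_CORRELATION_PAIRS = (
    ("vx_mean", "vc_mean"),
    ("vx_mean", "S"),
    ("vx_mean", "rho"),
    ("S", "rho"),
)


def correlation_report(
    condition_means: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_CORRELATION_PAIRS,
) -> pd.DataFrame:
    """Pearson correlation R across conditions for the declared pairs.

    Rows with a missing member of a pair are dropped pairwise; a pair
    needs at least 3 complete rows.
    """
    records = []
    for qa, qb in pairs:
        if qa not in condition_means.columns or qb not in condition_means.columns:
            continue
        sub = condition_means[[qa, qb]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({qa}, {qb})")
        r, p = stats.pearsonr(sub[qa], sub[qb])
        records.append({"quantity_a": qa, "quantity_b": qb, "R": r, "p": p, "n": len(sub)})
    return pd.DataFrame.from_records(records)
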