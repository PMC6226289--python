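"""End-to-end screen pipeline: per-condition flow, oscillation, foci,
material-property fitting, and the MCE map, with CSV/JSON artifacts.

Input layout: ``inputs/<condition>/<embryo>/{movie.tif, velocity.csv}``.
Every per-condition quantity is compared against the named negative
control: Wilcoxon rank-sum at 99% confidence for flow velocities and
foci statistics, 95% for the oscillation period, and a normal-CDF
z-test on the fitted hydrodynamic length and chirality index.  No
multiple-testing correction is applied by default (a Benjamini-Hochberg
option is exposed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import foci as foci_mod
from .activegel import CortexFit, fit_cortex, fit_significance
from .flow import (
    FlowSummary,
    chiral_counter_velocity,
    condition_histogram,
    correlation_report,
    mean_ap_velocity,
    time_averaged_profile,
    wilcoxon_compare,
)
from .geometry import AnalysisWindow, BinnedProfile, EmbryoGeometry, bin_profile
from .io import read_movie, read_velocity_fields
from .mce import FeatureTable, embed, mc_kernel, zscore_features
from .oscillation import autocorrelation, box_velocity_series, oscillation_period

__all__ = ["ScreenConfig", "ScreenReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Configuration of a full screen run."""

    input_dir: Path
    output_dir: Path
    control: str = "control"
    pixel_size: float = 0.25
    frame_interval: float = 5.0
    ap_extent: tuple[float, float] = (0.0, 54.0)
    y_mid: Optional[float] = None
    n_bins: int = 18
    stripe_height: float = 13.0
    start_frame: int = 0
    end_frame: Optional[int] = None
    foci_duration: float = 75.0
    confidence_flow: float = 0.99
    confidence_osc: float = 0.95
    lambda_bounds: tuple[float, float] = (1.0, 200.0)
    include_chirality: bool = True
    foci_decrease_epsilon: float = 1.0
    benjamini_hochberg: bool = False
    seed: int = 0

    def geometry(self) -> EmbryoGeometry:
        return EmbryoGeometry(
            ap_extent=tuple(self.ap_extent),
            y_mid=self.y_mid,
            n_bins=self.n_bins,
            stripe_height=self.stripe_height,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["input_dir"] = Path(raw["input_dir"])
        raw["output_dir"] = Path(raw["output_dir"])
        if "ap_extent" in raw:
            raw["ap_extent"] = tuple(raw["ap_extent"])
        if "lambda_bounds" in raw:
            raw["lambda_bounds"] = tuple(raw["lambda_bounds"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScreenReport:
    """Aggregated per-condition quantities and the embedding."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    embedding: Optional[pd.DataFrame]
    fits: dict[str, CortexFit]
    config_digest: str


def _discover(input_dir: Path) -> dict[str, list[Path]]:
    conditions: dict[str, list[Path]] = {}
    root = input_dir / "inputs" if (input_dir / "inputs").is_dir() else input_dir
    for cond_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        embryos = sorted(
            p for p in cond_dir.iterdir() if p.is_dir() and (p / "velocity.csv").exists()
        )
        if embryos:
            conditions[cond_dir.name] = embryos
    if not conditions:
        raise FileNotFoundError(f"no condition directories under {root}")
    return conditions


def _analyze_embryo(
    embryo_dir: Path, cfg: ScreenConfig, geom: EmbryoGeometry
) -> Optional[dict]:
    fields = read_velocity_fields(embryo_dir / "velocity.csv")
    movie = None
    movie_path = embryo_dir / "movie.tif"
    if movie_path.exists():
        movie = read_movie(movie_path, pixel_size=cfg.pixel_size, frame_interval=cfg.frame_interval)
    end = cfg.end_frame if cfg.end_frame is not None else len(fields) - 1
    window = AnalysisWindow(cfg.start_frame, end, foci_duration=cfg.foci_duration)

    profiles = []
    vx_frames, vc_frames = [], []
    for fi in window.frames():
        if fi >= len(fields):
            break
        frame = movie[fi] if movie is not None and fi < len(movie) else None
        prof = bin_profile(fields[fi], frame, geom)
        profiles.append(prof)
        vx_frames.append(mean_ap_velocity(prof, geom))
        vc_frames.append(chiral_counter_velocity(prof, geom))

    series = box_velocity_series(
        [fields[fi] for fi in window.frames() if fi < len(fields)], geom, cfg.frame_interval
    )
    tosc = oscillation_period(autocorrelation(series))

    S_frames, rho_frames = [], []
    if movie is not None:
        for fi in window.foci_frames(cfg.frame_interval):
            if fi >= len(movie):
                break
            stats = foci_mod.analyze_frame(
                movie[fi], geom, frame_index=fi, decrease_epsilon=cfg.foci_decrease_epsilon
            )
            if stats.S is not None:
                S_frames.append(stats.S)
            rho_frames.append(stats.rho)

    return {
        "profiles": profiles,
        "vx_frames": np.array(vx_frames),
        "vc_frames": np.array(vc_frames),
        "tosc": tosc,
        "S_frames": np.array(S_frames),
        "rho_frames": np.array(rho_frames),
    }


def _bh_adjust(pvals: pd.Series) -> pd.Series:
    p = pvals.dropna().sort_values()
    n = len(p)
    adj = p * n / np.arange(1, n + 1)
    adj = adj[::-1].cummin()[::-1].clip(upper=1.0)
    out = pd.Series(np.nan, index=pvals.index)
    out[adj.index] = adj
    return out


def run_pipeline(cfg: ScreenConfig) -> ScreenReport:
    """Run all stages over a directory of conditions and embryos.

    Per-embryo failures are logged and skipped; a condition without any
    analyzable embryo aborts the run.  Deterministic given config.
    """
    geom = cfg.geometry()
    conditions = _discover(cfg.input_dir)
    if cfg.control not in conditions:
        raise ValueError(f"control condition {cfg.control!r} not among inputs")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_cond: dict[str, dict] = {}
    for cond, embryo_dirs in conditions.items():
        embryos = []
        for edir in embryo_dirs:
            try:
                embryos.append(_analyze_embryo(edir, cfg, geom))
            except Exception:
                logger.exception("embryo %s failed; skipped", edir)
        if not embryos:
            raise RuntimeError(f"no analyzable embryos for condition {cond!r}")
        summaries = [
            FlowSummary(cond, f"e{idx}", e["vx_frames"], e["vc_frames"])
            for idx, e in enumerate(embryos)
        ]
        mean_profile = time_averaged_profile([e["profiles"] for e in embryos])
        fit = fit_cortex(
            mean_profile,
            include_chirality=cfg.include_chirality,
            lambda_bounds=cfg.lambda_bounds,
        )
        per_cond[cond] = {
            "embryos": embryos,
            "summaries": summaries,
            "profile": mean_profile,
            "fit": fit,
            "tosc": [e["tosc"] for e in embryos],
            "S_pool": np.concatenate([e["S_frames"] for e in embryos]),
            "rho_pool": np.concatenate([e["rho_frames"] for e in embryos]),
        }

    ctrl = per_cond[cfg.control]
    ctrl_vx = np.concatenate([s.vx_frames for s in ctrl["summaries"]])
    ctrl_vc = np.concatenate([s.vc_frames for s in ctrl["summaries"]])
    ctrl_tosc = [t for t in ctrl["tosc"] if t is not None]

    rows = []
    for cond, data in per_cond.items():
        vx_hist = condition_histogram(data["summaries"], "vx")
        vc_hist = condition_histogram(data["summaries"], "vc")
        tosc_vals = np.array([t for t in data["tosc"] if t is not None], dtype=float)
        fit = data["fit"]
        row = {
            "condition": cond,
            "n_embryos": len(data["embryos"]),
            "vx_mean": vx_hist.mean,
            "vx_sem": vx_hist.sem,
            "vc_mean": vc_hist.mean,
            "vc_sem": vc_hist.sem,
            "Tosc": float(np.mean(tosc_vals)) if tosc_vals.size else np.nan,
            "Tosc_sem": float(np.std(tosc_vals, ddof=1) / np.sqrt(tosc_vals.size))
            if tosc_vals.size > 1
            else np.nan,
            "S": float(np.mean(data["S_pool"])) if data["S_pool"].size else np.nan,
            "rho": float(np.mean(data["rho_pool"])) if data["rho_pool"].size else np.nan,
            "lambda": fit.params.lambda_um,
            "lambda_se": fit.se_lambda,
            "c": fit.c if fit.c is not None else np.nan,
            "c_se": fit.se_c if fit.se_c is not None else np.nan,
        }
        if cond == cfg.control:
            row.update(
                p_vx=np.nan, p_vc=np.nan, p_tosc=np.nan, p_lambda=np.nan, p_c=np.nan,
                sig_vx=False, sig_vc=False, sig_tosc=False, sig_lambda=False, sig_c=False,
            )
        else:
            p_vx, s_vx = wilcoxon_compare(
                vx_hist.pooled, ctrl_vx, confidence=cfg.confidence_flow
            )
            p_vc, s_vc = wilcoxon_compare(
                vc_hist.pooled, ctrl_vc, confidence=cfg.confidence_flow
            )
            if tosc_vals.size and len(ctrl_tosc):
                p_t, s_t = wilcoxon_compare(
                    tosc_vals, np.array(ctrl_tosc), confidence=cfg.confidence_osc
                )
            else:
                p_t, s_t = np.nan, False
            p_l, s_l = fit_significance(fit, ctrl["fit"], "lambda", cfg.confidence_flow)
            try:
                p_c, s_c = fit_significance(fit, ctrl["fit"], "c", cfg.confidence_flow)
            except ValueError:
                p_c, s_c = np.nan, False
            row.update(
                p_vx=p_vx, p_vc=p_vc, p_tosc=p_t, p_lambda=p_l, p_c=p_c,
                sig_vx=s_vx, sig_vc=s_vc, sig_tosc=s_t, sig_lambda=s_l, sig_c=s_c,
            )
        rows.append(row)

    table = pd.DataFrame(rows).set_index("condition")
    if cfg.benjamini_hochberg:
        for col in ("p_vx", "p_vc", "p_tosc", "p_lambda", "p_c"):
            table[col + "_bh"] = _bh_adjust(table[col])

    corr = None
    try:
        corr = correlation_report(table)
    except ValueError:
        corr = pd.DataFrame()

    embedding_df = None
    if len(table) >= 3:
        try:
            features = table[["rho", "vx_mean", "Tosc", "lambda", "c"]].copy()
            ztab = zscore_features(FeatureTable(data=features))
            kern = mc_kernel(ztab)
            emb = embed(kern)
            embedding_df = pd.DataFrame(
                emb.coords, columns=["dim1", "dim2"], index=ztab.data.index
            )
        except ValueError as exc:
            logger.warning("embedding skipped: %s", exc)

    table.to_csv(out / "screen_report.csv")
    if corr is not None and len(corr):
        corr.to_csv(out / "correlations.csv", index=False)
    if embedding_df is not None:
        embedding_df.to_csv(out / "embedding.csv")
    fits_json = {cond: data["fit"].to_dict() for cond, data in per_cond.items()}
    (out / "fits.json").write_text(json.dumps(fits_json, indent=2))
    digest = cfg.digest()
    (out / "run.log").write_text(
        json.dumps(
            {
                "config_digest": digest,
                "n_conditions": len(per_cond),
                "n_embryos": {c: len(d["embryos"]) for c, d in per_cond.items()},
            },
            indent=2,
        )
    )
    return ScreenReport(
        table=table,
        correlations=corr,
        embedding=embedding_df,
        fits={c: d["fit"] for c, d in per_cond.items()},
        config_digest=digest,
    )
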