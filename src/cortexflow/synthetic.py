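"""Synthetic cortical-flow data with known ground truth.

Every pipeline stage is testable without real embryo movies: the
generators here produce anterior-enriched intensity profiles, velocity
fields obeying the active-gel equations for chosen (lambda, alpha,
beta), pulsatile posterior velocity series, images of diffraction-
blurred myosin foci, and clustered per-condition feature tables.  Each
generator is a pure function of its parameters and seed, and ground
truth is serialized next to generated datasets.

Noise is additive Gaussian throughout (the simplest model supporting
SEM-based fitting).  Foci images are quantized to integer gray levels
by default, emulating camera digitization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .activegel import solve_flow_profile
from .geometry import BinnedProfile, EmbryoGeometry
from .io import Frame, Movie, VelocityField, write_movie, write_velocity_fields
from .mce import FEATURE_COLUMNS, FeatureTable

__all__ = [
    "SynthTruth",
    "default_geometry",
    "synth_intensity_profile",
    "model_velocity_profiles",
    "synth_binned_profile",
    "synth_velocity_data",
    "synth_pulsatile_series",
    "synth_foci_image",
    "synth_condition_table",
    "synth_screen",
]

# Nominal zygote dimensions (um): AP length 54 (18 bins of 3 um), height 33.
DEFAULT_AP_EXTENT = (0.0, 54.0)
DEFAULT_HEIGHT = 33.0


@dataclass
class SynthTruth:
    """Ground-truth parameters stored alongside every generated dataset."""

    seed: int
    lambda_true: Optional[float] = None
    alpha_true: Optional[float] = None
    beta_true: Optional[float] = None
    c_true: Optional[float] = None
    period_true: Optional[float] = None
    foci_count_true: Optional[int] = None
    foci_sigma_true: Optional[float] = None
    foci_density_true: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lambda_true is not None and self.lambda_true <= 0:
            raise ValueError("lambda_true must be positive")
        if self.foci_count_true is not None and self.foci_count_true < 0:
            raise ValueError("foci_count_true must be >= 0")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SynthTruth":
        return cls(**json.loads(Path(path).read_text()))


def default_geometry(y_mid: float = DEFAULT_HEIGHT / 2.0) -> EmbryoGeometry:
    return EmbryoGeometry(ap_extent=DEFAULT_AP_EXTENT, y_mid=y_mid)


def synth_intensity_profile(
    shape: str = "sigmoid",
    contrast: float = 2.0,
    n_bins: int = 18,
    midpoint: float = 0.5,
    steepness: float = 12.0,
    custom: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Anterior-high per-bin myosin intensity profile.

    ``sigmoid``: I(u) = 1 + contrast / (1 + exp(steepness (u - midpoint)))
    with u the bin centre on [0, 1]; anterior/posterior ratio approaches
    1 + contrast.  ``step``: two levels split at the midpoint.
    ``custom`` passes a profile through unchanged.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    u = (np.arange(n_bins) + 0.5) / n_bins
    if shape == "sigmoid":
        return 1.0 + contrast / (1.0 + np.exp(steepness * (u - midpoint)))
    if shape == "step":
        return np.where(u < midpoint, 1.0 + contrast, 1.0)
    if shape == "custom":
        if custom is None:
            raise ValueError("custom profile requires the 'custom' array")
        arr = np.asarray(custom, dtype=float)
        if arr.size != n_bins:
            raise ValueError("custom profile length must equal n_bins")
        return arr
    raise ValueError("shape must be 'sigmoid', 'step' or 'custom'")


def model_velocity_profiles(
    I_bins: np.ndarray,
    geom: EmbryoGeometry,
    lambda_um: float,
    alpha_eff: float,
    beta_eff: float,
    n_grid: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless model velocities at the bin centres.

    The per-bin intensity is normalized to unit mean and linearly
    interpolated onto an ``n_grid`` fine grid spanning the bin centres
    (the same representation the fitting routine uses); the boundary-
    value problems are solved with zero Dirichlet conditions at both
    ends and sampled back at the bin centres.
    """
    xb = geom.bin_centers
    I_norm = np.asarray(I_bins, dtype=float)
    I_norm = I_norm / np.mean(I_norm)
    x_fine = np.linspace(xb[0], xb[-1], n_grid)
    I_fine = np.interp(x_fine, xb, I_norm)
    vx_fine, vy_fine = solve_flow_profile(
        I_fine, x_fine, lambda_um, alpha_eff, beta_eff
    )
    return np.interp(xb, x_fine, vx_fine), np.interp(xb, x_fine, vy_fine)


def synth_binned_profile(
    I_bins: np.ndarray,
    geom: EmbryoGeometry,
    lambda_um: float = 18.0,
    alpha_eff: float = 300.0,
    beta_eff: Optional[float] = None,
    c: float = 0.321,
    noise_sd: float = 0.0,
    relative_noise: float = 0.0,
    n_samples_per_bin: int = 10,
    seed: int = 0,
) -> tuple[BinnedProfile, SynthTruth]:
    """Binned profile whose velocities obey the active-gel model.

    ``beta_eff`` defaults to ``c * alpha_eff``.  ``noise_sd`` adds
    Gaussian noise of that SD (um/min) to each bin velocity;
    ``relative_noise`` perturbs each velocity multiplicatively,
    v -> v * (1 + N(0, relative_noise)).
    """
    if beta_eff is None:
        beta_eff = c * alpha_eff
    vx, vy = model_velocity_profiles(I_bins, geom, lambda_um, alpha_eff, beta_eff)
    rng = np.random.default_rng(seed)
    if relative_noise > 0:
        vx = vx * (1.0 + rng.normal(0.0, relative_noise, vx.size))
        vy = vy * (1.0 + rng.normal(0.0, relative_noise, vy.size))
    if noise_sd > 0:
        vx = vx + rng.normal(0.0, noise_sd, vx.size)
        vy = vy + rng.normal(0.0, noise_sd, vy.size)
    nb = geom.n_bins
    sem = np.full(nb, noise_sd if noise_sd > 0 else np.nan)
    profile = BinnedProfile(
        bin_centers=geom.bin_centers,
        I=np.asarray(I_bins, dtype=float),
        vx=vx,
        vy=vy,
        sem_I=np.full(nb, np.nan),
        sem_vx=sem,
        sem_vy=sem,
        n_samples=np.full(nb, n_samples_per_bin),
    )
    truth = SynthTruth(
        seed=seed,
        lambda_true=lambda_um,
        alpha_true=alpha_eff,
        beta_true=beta_eff,
        c_true=beta_eff / alpha_eff if alpha_eff else None,
    )
    return profile, truth


def synth_velocity_data(
    I_bins: np.ndarray,
    geom: EmbryoGeometry,
    lambda_um: float = 18.0,
    alpha_eff: float = 300.0,
    beta_eff: float = 0.321 * 300.0,
    noise_sd: float = 0.0,
    n_embryos: int = 1,
    n_frames: int = 10,
    seed: int = 0,
    node_spacing: float = 2.0,
    y_extent: float = DEFAULT_HEIGHT,
    pulsation_amplitude: float = 0.0,
    pulsation_period: float = 33.0,
    frame_interval: float = 5.0,
) -> tuple[list[list[VelocityField]], SynthTruth]:
    """Per-embryo sequences of velocity fields obeying the model.

    Node velocities are the boundary-value solution sampled at node x
    positions (identical across y), optionally modulated in time by a
    multiplicative sinusoidal pulsation, plus i.i.d. Gaussian noise per
    node and frame.  The same seed reproduces identical output.
    """
    vx_b, vy_b = model_velocity_profiles(I_bins, geom, lambda_um, alpha_eff, beta_eff)
    xb = geom.bin_centers
    x_min, x_max = geom.ap_extent
    xs = np.arange(x_min + node_spacing / 2.0, x_max, node_spacing)
    ys = np.arange(node_spacing / 2.0, y_extent, node_spacing)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    vx_nodes = np.interp(gx, xb, vx_b)
    vy_nodes = np.interp(gx, xb, vy_b)

    rng = np.random.default_rng(seed)
    embryos = []
    for _ in range(n_embryos):
        fields = []
        for fi in range(n_frames):
            t = fi * frame_interval
            mod = 1.0 + pulsation_amplitude * np.sin(2 * np.pi * t / pulsation_period)
            vx = vx_nodes * mod
            vy = vy_nodes * mod
            if noise_sd > 0:
                vx = vx + rng.normal(0.0, noise_sd, vx.size)
                vy = vy + rng.normal(0.0, noise_sd, vy.size)
            fields.append(
                VelocityField(x=gx.copy(), y=gy.copy(), vx=vx, vy=vy, frame_index=fi)
            )
        embryos.append(fields)
    truth = SynthTruth(
        seed=seed,
        lambda_true=lambda_um,
        alpha_true=alpha_eff,
        beta_true=beta_eff,
        c_true=beta_eff / alpha_eff if alpha_eff else None,
        period_true=pulsation_period if pulsation_amplitude > 0 else None,
    )
    return embryos, truth


def synth_pulsatile_series(
    period: float = 33.0,
    amplitude: float = 3.0,
    mean_level: float = -6.0,
    noise_sd: float = 0.0,
    duration: float = 300.0,
    dt: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoidal box-velocity time series: mean + A sin(2 pi t / P) + noise.

    Returns (t, v).  Raises if the period cannot be resolved (P < 2 dt)
    or the duration covers fewer than two periods.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if period < 2 * dt:
        raise ValueError("period below the 2*dt resolution limit")
    if duration < 2 * period:
        raise ValueError("duration must cover at least two periods")
    t = np.arange(0.0, duration + dt / 2.0, dt)
    v = mean_level + amplitude * np.sin(2 * np.pi * t / period)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return t, v


def _place_hardcore(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_sep: float,
    retry_cap: int = 10_000,
) -> np.ndarray:
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        if attempts >= retry_cap:
            raise RuntimeError(
                f"could not place {n} foci at min separation {min_sep} within {retry_cap} attempts"
            )
        p = rng.uniform(lo, hi)
        attempts += 1
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts) if pts else np.empty((0, 2))


def synth_foci_image(
    n_foci: int,
    sigma_um: float = 0.6,
    image_size_um: tuple[float, float] = (27.0, 13.0),
    pixel_size: float = 0.26,
    amplitude: float = 600.0,
    amplitude_cv: float = 0.0,
    background: float = 20.0,
    noise_sd: float = 0.5,
    min_separation: float = 2.0,
    margin_um: float = 1.5,
    speckle_density: float = 0.10,
    speckle_amp: tuple[float, float] = (48.0, 240.0),
    speckle_sigma: float = 0.1,
    quantize: bool = True,
    seed: int = 0,
) -> tuple[Frame, SynthTruth]:
    """Image of diffraction-blurred myosin foci with known ground truth.

    Isotropic Gaussian spots (SD ``sigma_um``) are placed by hard-core
    rejection sampling (pairwise separation >= ``min_separation``,
    centres at least ``margin_um`` from the border) on a constant
    background with additive Gaussian noise.  Spot amplitudes are
    lognormal with coefficient of variation ``amplitude_cv`` (a dim
    subpopulation exercises the intensity threshold).

    Two camera/biology realism features matter for detection and are on
    by default: ``quantize`` rounds to integer gray levels (camera
    digitization; a flat background then yields almost no spurious
    strict window maxima), and a population of point-like dim myosin
    speckles (diffraction-scale sigma ``speckle_sigma``, count
    ``speckle_density`` per um^2, peak amplitudes uniform in
    ``speckle_amp``) models unincorporated minifilament signal.  The
    speckles matter because the detection's dim-candidate discard
    (candidate mean minus 0.5 SD) implicitly assumes a dim candidate
    subpopulation; on an empty background it would instead clip the
    bottom of the genuine foci distribution.  Truth density is
    n_foci / image area.
    """
    w_um, h_um = image_size_um
    nx = int(round(w_um / pixel_size))
    ny = int(round(h_um / pixel_size))
    rng = np.random.default_rng(seed)
    lo = np.array([margin_um, margin_um])
    hi = np.array([w_um - margin_um, h_um - margin_um])
    centers = _place_hardcore(rng, n_foci, lo, hi, min_separation)

    if amplitude_cv > 0:
        s2 = np.log1p(amplitude_cv**2)
        amps = rng.lognormal(np.log(amplitude) - s2 / 2.0, np.sqrt(s2), n_foci)
    else:
        amps = np.full(n_foci, float(amplitude))

    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(x, y)
    img = np.full((ny, nx), float(background))
    for (cx, cy), a in zip(centers, amps):
        img += a * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2.0 * sigma_um**2))
    n_speck = int(round(speckle_density * w_um * h_um))
    for _ in range(n_speck):
        cx, cy = rng.uniform([0.0, 0.0], [w_um, h_um])
        a = rng.uniform(*speckle_amp)
        img += a * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2.0 * speckle_sigma**2))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    if quantize:
        img = np.clip(np.round(img), 0.0, None)
    frame = Frame(img, pixel_size=pixel_size)
    truth = SynthTruth(
        seed=seed,
        foci_count_true=n_foci,
        foci_sigma_true=sigma_um,
        foci_density_true=n_foci / (w_um * h_um),
    )
    return frame, truth


def synth_condition_table(
    n_conditions: int,
    cluster_centers: Sequence[Sequence[float]],
    within_sd: float,
    seed: int = 0,
) -> tuple[FeatureTable, np.ndarray]:
    """Clustered per-condition 5-feature table with recovery labels.

    Conditions are assigned round-robin to the given cluster centres and
    drawn Gaussian (SD ``within_sd``) around them.
    """
    centers = np.asarray(cluster_centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"cluster centres must be 5-vectors {FEATURE_COLUMNS}")
    if centers.shape[0] < 2:
        raise ValueError("need at least 2 cluster centres")
    if within_sd < 0:
        raise ValueError("within_sd must be non-negative")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_conditions) % centers.shape[0]
    rows = centers[labels] + rng.normal(0.0, within_sd, (n_conditions, centers.shape[1]))
    df = pd.DataFrame(
        rows,
        columns=list(FEATURE_COLUMNS),
        index=[f"cond_{i:02d}" for i in range(n_conditions)],
    )
    return FeatureTable(data=df), labels


# ---------------------------------------------------------------------------
# Full synthetic screen (movies + velocity CSVs on disk)

DEFAULT_SCREEN_CONDITIONS = {
    # name -> parameter overrides relative to the control condition
    "control": {},
    "lambda_half": {"lambda_um": 9.0, "pulsation_period": 25.0},
    "slow_flow": {"alpha_eff": 150.0, "beta_eff": 0.321 * 150.0, "pulsation_period": 45.0},
}


def synth_screen(
    out_dir: str | Path,
    conditions: Optional[dict[str, dict]] = None,
    n_embryos: int = 4,
    n_frames: int = 60,
    seed: int = 0,
    pixel_size: float = 0.25,
    velocity_noise_sd: float = 0.3,
    foci_density: float = 0.12,
    foci_amplitude: float = 120.0,
    image_noise_sd: float = 1.0,
) -> Path:
    """Write a directory tree of synthetic movies and velocity fields.

    Layout: ``inputs/<condition>/<embryo>/{movie.tif, velocity.csv}``
    plus a ``truth.json`` per condition.  The control condition uses
    lambda = 18 um and chirality index c = 0.321 with a sigmoid
    anterior-high intensity profile; movies carry that smooth profile
    plus uniformly seeded foci so that every analysis stage has signal.
    """
    from scipy import ndimage

    out = Path(out_dir)
    conditions = dict(DEFAULT_SCREEN_CONDITIONS if conditions is None else conditions)
    geom = default_geometry()
    I_bins = synth_intensity_profile("sigmoid", contrast=2.0, n_bins=geom.n_bins)
    base = {
        "lambda_um": 18.0,
        "alpha_eff": 300.0,
        "beta_eff": 0.321 * 300.0,
        "pulsation_period": 33.0,
    }
    w_um = geom.ap_extent[1]
    h_um = DEFAULT_HEIGHT
    nx, ny = int(round(w_um / pixel_size)), int(round(h_um / pixel_size))
    x_px = (np.arange(nx) + 0.5) * pixel_size

    # Smooth AP intensity carried by the image base; foci are resampled
    # every frame (cortical turnover), so their expected contribution is
    # a constant offset and the intensity profile used for velocity
    # generation matches the expected binned image intensity.
    base_scale = 30.0
    sigma_um = 0.6
    sigma_px = sigma_um / pixel_size
    I_base = np.interp(x_px, geom.bin_centers, I_bins)
    foci_offset = foci_density * foci_amplitude * 2 * np.pi * sigma_um**2
    background = 10.0
    I_gen_bins = background + base_scale * I_bins + foci_offset
    n_foci = int(round(foci_density * w_um * h_um))
    base_img = background + base_scale * I_base[None, :] * np.ones((ny, 1))

    rng_master = np.random.default_rng(seed)
    for cond, overrides in conditions.items():
        params = {**base, **overrides}
        cond_dir = out / "inputs" / cond
        cond_dir.mkdir(parents=True, exist_ok=True)
        cond_seed = int(rng_master.integers(0, 2**31 - 1))
        fields_by_embryo, truth = synth_velocity_data(
            I_gen_bins,
            geom,
            lambda_um=params["lambda_um"],
            alpha_eff=params["alpha_eff"],
            beta_eff=params["beta_eff"],
            noise_sd=velocity_noise_sd,
            n_embryos=n_embryos,
            n_frames=n_frames,
            seed=cond_seed,
            pulsation_amplitude=0.4,
            pulsation_period=params["pulsation_period"],
        )
        truth.save(cond_dir / "truth.json")
        rng = np.random.default_rng(cond_seed + 1)
        for ei, fields in enumerate(fields_by_embryo):
            edir = cond_dir / f"embryo_{ei:02d}"
            edir.mkdir(exist_ok=True)
            write_velocity_fields(edir / "velocity.csv", fields)
            frames = []
            for fi in range(n_frames):
                # impulse rendering: foci become Gaussian spots of peak
                # `foci_amplitude` after the blur
                impulses = np.zeros((ny, nx))
                rows = rng.integers(0, ny, n_foci)
                cols = rng.integers(0, nx, n_foci)
                np.add.at(impulses, (rows, cols), foci_amplitude * 2 * np.pi * sigma_px**2)
                img = base_img + ndimage.gaussian_filter(impulses, sigma_px)
                img = img + rng.normal(0.0, image_noise_sd, img.shape)
                img = np.clip(np.round(img), 0.0, None)
                frames.append(Frame(img, pixel_size=pixel_size, time=fi * 5.0))
            write_movie(edir / "movie.tif", Movie(frames, frame_interval=5.0), dtype="uint16")
    return out
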