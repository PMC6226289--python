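# Methods

## Geometry and binning

The embryo's AP axis is divided into 18 equal bins (1-based indices),
anterior at `x_min`; the default extent is 54 µm, so bins are 3 µm
wide. Spatial averages are restricted to a 13 µm-high stripe centred on
the midline. Bins are half-open `[left, right)` with the last bin
closed, so nodes and pixels are counted exactly once. Pixel centres sit
at `(i + 0.5) · pixel_size`. The posterior flow region is bins 13–16,
the anterior region bins 3–6; the foci stripe is 27 µm wide centred on
the bin 7/8 boundary; the oscillation box is 6 × 6 µm centred on the
bin 14/15 boundary, midline-centred. Bins without in-stripe samples are
flagged missing and excluded downstream, never zero-filled. The
AP extent and midline are supplied by configuration: axis detection and
segmentation are out of scope.

## Flow statistics and comparisons

Per frame, v̄x is the arithmetic mean of binned vx over the posterior
bins, and v̄c the posterior-minus-anterior mean of binned vy. Condition
histograms and means pool per-frame values across all embryos of a
condition; the SEM is computed over the pooled values. Time-averaged
profiles are two-stage: mean over frames within each embryo, then mean
and SEM across embryos.

The Wilcoxon rank-sum test uses midranks. Exact p-values are obtained
by full enumeration of group assignments whenever
`C(n_a + n_b, n_a) ≤ 2·10^5` (this covers all small-sample cases);
larger problems use the normal approximation with tie-corrected
variance and continuity correction. The two-sided exact p is
`P(|W − E[W]| ≥ |w_obs − E[W]|)` under the permutation distribution.
Confidence conventions: 99 % for v̄x, v̄c, S, ρ, λ and c; 95 % for
T_osc. No multiple-testing correction is applied by default
(a Benjamini–Hochberg column is available via configuration).

## Oscillation period

The box-velocity series (per-frame mean vx over the posterior box) is
mean-subtracted and autocorrelated with the biased estimator
`A(k) = Σ δv(t) δv(t+k) / Σ δv(t)²` for lags up to half the series
length; this guarantees `|A(k)| ≤ 1` and A(0) = 1. T_osc is the lag of
the first strict local maximum (plateau peaks take the smallest lag of
the plateau); series without a peak, or without variance above the
float rounding floor, are discarded from the condition mean, which is
taken across embryos. The estimate is quantized to the frame interval:
a 33 s rhythm sampled at 5 s reads out as 30 or 35 s.

## Foci structure

**Size.** The anterior stripe's spatial autocorrelation is computed by
FFT with zero padding (no wraparound) on the mean-subtracted patch and
normalized to 1 at zero shift. The radial profile samples the map
bilinearly at `max(8, round(2πr))` angles per integer pixel radius. S
is the radius of the first strict local minimum (the zero-shift value
is prepended so a minimum at the first radius is detectable). Because
the patch mean is subtracted, even a single blob's ACF has a shallow
negative lobe; "no characteristic size" is therefore a property of
truly monotone profiles, not of every isolated-spot image. The biased
(triangular-windowed) ACF pulls minima slightly inward on small
patches: a 10 µm stripe pattern reads S = 5.7 µm on a 27 × 13 µm patch
and converges to 5.98 µm (Bessel-zero prediction 6.10 µm) on larger
ones.

**Density.** Detection follows four steps: (1) candidates are pixels
that are the strict maximum of the ~2 µm window centred on them
(window converted to the nearest odd pixel count; candidates whose
window is truncated by the border are excluded); (2) candidates closer
than 1 µm are merged by single linkage, keeping the brighter pixel
(ties: first in row-major order); (3) candidates whose window-mean
intensity falls below the candidate mean minus 0.5 sample standard
deviations are discarded as significantly dimmer; (4) pairs whose
connecting segment (sampled bilinearly at pixel-resolution steps)
lacks a contiguous decreasing run of at least 1 µm are merged, brighter
member kept, iterating over pairs by increasing separation until
stable. ρ is the surviving count over the stripe area. A decrease
tolerance `decrease_epsilon` (intensity units, default 0) lets small
noise-induced upticks count as part of a decreasing run on noisy data;
analyses of the synthetic screens use epsilon equal to the image noise
scale (1 gray level). The whole procedure is invariant under affine
intensity transforms with positive scale (epsilon = 0).

Two structural properties of this published procedure matter for
interpretation. First, step 3 presupposes a dim candidate
subpopulation: applied to a homogeneous population of equally bright
foci it discards the bottom ~31 % (Φ(−0.5)) regardless of how tight the
distribution is. Real cortical images supply dim structures; synthetic
images must too (see below). Second, the 1 µm ridge-run rule makes
~2 µm the design resolution: pairs separated by 2.0–2.25 µm are merged
because the descending run between them measures just under 1 µm after
pixel sampling.

## Active-gel solver and fit

The two boundary-value problems (`λ² v″ − v = f` and the torque
equation with coefficient λ²/2, hence chiral decay length λ/√2) are
solved by second-order central differences and a tridiagonal banded
solve; ∂x I uses central differences. Manufactured-solution error is
~3.6·10⁻⁵ at 200 grid points with a convergence ratio of 4 per grid
doubling. The inline shorthand "λ = η/γ" seen in the literature is
treated as λ² = η/γ, as dimensional consistency of the equations
requires.

The fit normalizes intensity to unit mean (fluorescence units are
arbitrary; λ and c are invariant), interpolates it linearly onto a
200-point uniform grid spanning the non-missing bin centres, and takes
Dirichlet boundary values from the measured velocities at the two
extreme bins. For fixed λ the model is linear in α and β, so those are
solved in closed form; λ is found by a 60-point log-spaced scan over
[1, 200] µm followed by bounded scalar minimization in the best
bracket (the scan guards against local minima). vx and vy residuals
enter one joint SSR; the vy term is dropped in chirality-off mode
(used when the chiral fit quality is poor, e.g. strongly elastic
phenotypes). Standard errors come from the central finite-difference
Hessian of the SSR (relative step 10⁻⁴) via `cov = 2 s² H⁻¹`,
`s² = SSR/(n − p)`; SE(c) by first-order propagation using the (α, β)
covariance block. Residuals are unweighted by default ("least
squares"); inverse-SEM² weighting is available. Fits at a λ bound are
flagged. Fitted-parameter comparisons between conditions use the
two-sided normal z-test on the Hessian-based SEs.

## Synthetic data

The generators define the study conditions; each is a pure function of
its parameters and seed, and ground truth is serialized next to the
data (JSON).

- **Intensity profiles**: anterior-high sigmoid (default contrast 2,
  anterior/posterior ratio 3) or step, on 18 bins.
- **Velocity data**: the forward solution of the model (same intensity
  interpolation and solver as the fit, zero Dirichlet ends) sampled at
  bin centres or onto 2-D node grids, optionally modulated by a
  multiplicative sinusoidal pulsation and additive or relative Gaussian
  noise. Defaults: λ = 18 µm, c = 0.321 (control-like), forcing scaled
  to a few µm/min.
- **Pulsatile series**: `mean + A sin(2πt/P) + noise`, default P = 33 s
  at dt = 5 s.
- **Foci images**: hard-core-placed Gaussian spots (σ = 0.6 µm, minimum
  separation 2 µm, 1.5 µm border margin) on a constant background with
  Gaussian noise, rounded to integer gray levels (camera digitization),
  plus a fixed-count population of point-like dim myosin speckles
  (σ = 0.1 µm, 0.10 µm⁻², peak amplitudes 48–240 vs. focus amplitude
  600, background 20, noise SD 0.5). The quantized near-flat background
  suppresses the spurious strict-maxima rate (~1 per window area) that
  any continuous noise would produce, and the speckles supply the dim
  candidate population that step 3 requires. Under these conditions the
  density recovery within 15 % of truth succeeds in ~94 % of images at
  0.02 and 0.05 µm⁻² and ~75 % at 0.10 µm⁻²; the shortfall at the
  highest density comes from the ridge-rule resolution limit (minimum
  separation equals exactly twice the ridge run), not from noise.
- **Screens**: `inputs/<condition>/<embryo>/{movie.tif, velocity.csv}`
  plus truth JSON. Movies carry a smooth sigmoid base plus foci
  resampled every frame (turnover), so the time-averaged binned
  intensity converges to the profile that generated the velocities.
  Default conditions: control; λ halved (9 µm, faster pulsation);
  forcing halved (slower flow, slower pulsation).

What the generators do **not** emulate: photobleaching, shot noise,
foci advection and fission/fusion, cortical turnover kinetics, embryo
curvature and segmentation errors, PIV artefacts. Passing recovery
tests therefore demonstrates correctness of the analysis chain under
the stated noise models, not robustness to every failure mode of real
microscopy.

## MCE embedding

Features (ρ, v̄x, T_osc, λ, c) are z-scored column-wise (sample SD);
conditions with an undefined chirality index but near-zero
counter-rotation may be imputed c = 0 explicitly — no other silent
imputation happens (incomplete conditions are dropped with a warning).
The "correlation norm" is the correlation distance `1 − r` between
condition feature vectors. The minimum curvilinear kernel is the matrix
of path lengths over the Kruskal MST of the complete distance graph
(ties broken lexicographically), a tree metric by construction. The
default embedding double-centres the squared kernel (classical-MDS
style) and takes the top-2 spectral coordinates; a non-centred SVD
variant is available since either reading of the original procedure is
possible. Axis signs are fixed by making each axis's largest-magnitude
loading positive. Cluster assignment is deliberately left manual (as in
the original screen); `kmedoids_labels` is a convenience only.

## Pipeline

`run_pipeline` discovers `inputs/<condition>/<embryo>/`, runs binning,
flow statistics, oscillation, foci analysis (first 75 s of the window),
per-condition profile averaging and model fitting, significance tests
against the named control, cross-quantity Pearson correlations, and the
MCE map, writing CSV/JSON artifacts and a run log with a config digest.
Per-embryo failures are logged and skipped; everything is deterministic
given the inputs and configuration.

## Problem sizes

Default test and acceptance workloads use 18-bin profiles, 200-point
solver grids, 50-replicate noisy-fit ensembles, 100-seed oscillation
ensembles, 50 synthetic stripes (27 × 13 µm at 0.26 µm/pixel) for foci
recovery, 24-condition embedding tables, and a 3 × 4 × 60-frame screen
(54 × 33 µm embryos at 0.25 µm/pixel). These sizes were chosen so the
whole suite exercises every stage at meaningful statistical power while
remaining quick to run on a laptop.
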