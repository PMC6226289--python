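import numpy as np
import pytest

from cortexflow.foci import (
    detect_foci,
    foci_density,
    foci_size,
    radial_average,
    spatial_autocorrelation,
)
from cortexflow.synthetic import synth_foci_image


def gaussians(centers_um, amps, size_um=(20.0, 20.0), ps=0.2, sigma=0.6, bg=0.0):
    nx, ny = round(size_um[0] / ps), round(size_um[1] / ps)
    x = (np.arange(nx) + 0.5) * ps
    y = (np.arange(ny) + 0.5) * ps
    gx, gy = np.meshgrid(x, y)
    img = np.full((ny, nx), float(bg))
    for (cx, cy), a in zip(centers_um, amps):
        img += a * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
    return img


class TestSpatialAutocorrelation:
    def test_unity_at_zero_shift(self, rng):
        acf = spatial_autocorrelation(rng.random((12, 17)))
        assert acf[11, 16] == pytest.approx(1.0)

    def test_matches_direct_shift_and_sum_oracle(self, rng):
        patch = rng.random((16, 16))
        acf = spatial_autocorrelation(patch)
        d = patch - patch.mean()
        norm = np.sum(d * d)
        H, W = d.shape
        for dr in (-7, -2, 0, 3, 9):
            for dc in (-5, 0, 4, 11):
                total = 0.0
                for r in range(H):
                    for c in range(W):
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < H and 0 <= c2 < W:
                            total += d[r, c] * d[r2, c2]
                assert acf[H - 1 + dr, W - 1 + dc] == pytest.approx(
                    total / norm, abs=1e-10
                )

    def test_cosine_patch_oscillates_with_pattern_period(self):
        # I(x) = cos(2 pi x / p): the x-axis cut of the ACF is cos(2 pi dx / p)
        # times the zero-padding triangle window
        ps, p_um, W = 0.2, 4.0, 20.0
        nx = round(W / ps)
        x = (np.arange(nx) + 0.5) * ps
        patch = np.tile(np.cos(2 * np.pi * x / p_um), (40, 1))
        acf = spatial_autocorrelation(patch)
        row = acf[39]  # zero y-shift
        for dx_um in (1.0, 2.0, 3.0, 4.0):
            dx = round(dx_um / ps)
            expected = np.cos(2 * np.pi * dx_um / p_um) * (1 - dx / nx)
            # finite-window boundary terms allow a few percent slack
            assert row[nx - 1 + dx] == pytest.approx(expected, abs=0.05)

    def test_constant_patch_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spatial_autocorrelation(np.ones((10, 10)))

    def test_small_patch_rejected(self):
        with pytest.raises(ValueError):
            spatial_autocorrelation(np.random.rand(4, 4))


class TestRadialAverage:
    def test_radially_symmetric_gaussian_recovered(self):
        n = 41
        yy, xx = np.mgrid[:n, :n] - n // 2
        sig = 6.0
        acf = np.exp(-(xx**2 + yy**2) / (2 * sig**2))
        radii, prof = radial_average(acf, pixel_size=1.0)
        for r, v in zip(radii[:12], prof[:12]):
            assert v == pytest.approx(np.exp(-(r**2) / (2 * sig**2)), abs=0.01)

    def test_constant_map_gives_constant_profile(self):
        radii, prof = radial_average(np.full((21, 21), 0.7), pixel_size=0.5)
        assert np.allclose(prof, 0.7)

    def test_matches_dense_quadrature_oracle(self, rng):
        from scipy import ndimage

        acf = ndimage.gaussian_filter(rng.normal(size=(31, 31)), 2.0)
        radii, prof = radial_average(acf, pixel_size=1.0)
        cy = cx = 15
        for i, r in enumerate(range(1, 9)):
            n_ang = 10 * max(8, round(2 * np.pi * r))
            th = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
            dense = ndimage.map_coordinates(
                acf, [cy + r * np.sin(th), cx + r * np.cos(th)], order=1
            ).mean()
            scale = max(abs(dense), 1e-2)
            assert abs(prof[i] - dense) / scale < 0.05


class TestFociSize:
    def test_monotone_profile_has_no_characteristic_size(self):
        # a monotonically decaying radial ACF carries no spatial period
        radii = np.arange(1, 30) * 0.2
        prof = np.exp(-radii / 2.0)
        assert foci_size(radii, prof) is None

    def test_stripe_pattern_matches_bessel_zero(self):
        # radial average of cos(2 pi dx / p) is J0(2 pi r / p);
        # first minimum at r = 3.8317 p / (2 pi) = 0.61 p
        ps, p_um = 0.26, 10.0
        nx, ny = round(54 / ps), round(27 / ps)
        x = (np.arange(nx) + 0.5) * ps
        patch = np.tile(50 * np.cos(2 * np.pi * x / p_um) + 100, (ny, 1))
        radii, prof = radial_average(spatial_autocorrelation(patch), ps)
        S = foci_size(radii, prof)
        assert S == pytest.approx(6.1, abs=0.3)

    def test_lattice_spacing_matches_brute_force_first_minimum(self):
        centers = [(x, y) for x in (3.0, 9.0, 15.0) for y in (3.0, 9.0, 15.0)]
        img = gaussians(centers, [10.0] * 9, size_um=(18.0, 18.0))
        radii, prof = radial_average(spatial_autocorrelation(img), 0.2)
        S = foci_size(radii, prof)
        idx = next(
            i for i in range(1, len(prof) - 1)
            if prof[i - 1] > prof[i] < prof[i + 1]
        )
        assert S == pytest.approx(radii[idx])


# --- literal four-step reference implementation (plain loops) ---------------

def _oracle_odd_window(extent_um, ps):
    n = int(round(extent_um / ps))
    if n % 2 == 0:
        n += 1 if (extent_um / ps) >= n else -1
    return max(n, 3)


def _oracle_bilinear(img, r, c):
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r0 = min(max(r0, 0), img.shape[0] - 2) if img.shape[0] > 1 else 0
    c0 = min(max(c0, 0), img.shape[1] - 2) if img.shape[1] > 1 else 0
    fr, fc = r - r0, c - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r0 + 1, c0] * fr * (1 - fc)
        + img[r0, c0 + 1] * (1 - fr) * fc
        + img[r0 + 1, c0 + 1] * fr * fc
    )


def brute_force_detect(img, ps, window_um=2.0, merge_um=1.0, k=0.5, ridge_um=1.0, eps=0.0):
    H, W = img.shape
    w = _oracle_odd_window(window_um, ps)
    half = w // 2
    # step 1: strict maxima of the centred window, border excluded
    cands = []
    for r in range(half, H - half):
        for c in range(half, W - half):
            win = img[r - half : r + half + 1, c - half : c + half + 1].copy()
            center = win[half, half]
            win[half, half] = -np.inf
            if center > win.max():
                cands.append((r, c))
    if not cands:
        return np.empty((0, 2))
    # step 2: single-linkage merge below the merge radius, keep brighter
    n = len(cands)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            d = np.hypot(cands[i][0] - cands[j][0], cands[i][1] - cands[j][1])
            adj[i][j] = d < merge_um / ps
    comp = [-1] * n
    cid = 0
    for i in range(n):
        if comp[i] == -1:
            stack = [i]
            while stack:
                u = stack.pop()
                if comp[u] != -1:
                    continue
                comp[u] = cid
                stack.extend(v for v in range(n) if adj[u][v] and comp[v] == -1)
            cid += 1
    kept = []
    for g in range(cid):
        members = [i for i in range(n) if comp[i] == g]
        best = max(members, key=lambda i: (img[cands[i]], -i))
        kept.append(best)
    coords = [cands[i] for i in sorted(kept)]
    # step 3: discard candidates dimmer than mean - k * SD of window means
    def wmean(rc):
        r, c = int(rc[0]), int(rc[1])
        return img[r - half : r + half + 1, c - half : c + half + 1].mean()

    if len(coords) >= 2:
        wms = [wmean(rc) for rc in coords]
        thr = np.mean(wms) - k * np.std(wms, ddof=1)
        coords = [rc for rc, wm in zip(coords, wms) if wm >= thr]
    # step 4: ridge merging by increasing separation until stable
    coords = [np.array(rc, dtype=float) for rc in coords]
    changed = True
    while changed and len(coords) >= 2:
        changed = False
        pairs = sorted(
            (float(np.hypot(*(coords[i] - coords[j]))), i, j)
            for i in range(len(coords))
            for j in range(i + 1, len(coords))
        )
        for dist, i, j in pairs:
            nstep = max(1, int(round(dist)))
            ts = np.linspace(0.0, 1.0, nstep + 1)
            vals = [
                _oracle_bilinear(
                    img,
                    coords[i][0] + t * (coords[j][0] - coords[i][0]),
                    coords[i][1] + t * (coords[j][1] - coords[i][1]),
                )
                for t in ts
            ]
            best = run = 0
            for a, b in zip(vals[:-1], vals[1:]):
                if b - a < eps:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
            if best * (dist / nstep) * ps < ridge_um:
                vi = img[int(round(coords[i][0])), int(round(coords[i][1]))]
                vj = img[int(round(coords[j][0])), int(round(coords[j][1]))]
                del coords[j if vi >= vj else i]
                changed = True
                break
    out = np.array(
        [[(c + 0.5) * ps, (r + 0.5) * ps] for r, c in coords]
    ) if coords else np.empty((0, 2))
    return out


class TestDetectFoci:
    def test_constant_image_has_no_foci(self):
        fs = detect_foci(np.full((40, 40), 7.0), pixel_size=0.25)
        assert fs.count == 0

    def test_five_separated_gaussians_detected(self):
        # centres off the pixel lattice so no symmetric float ties occur;
        # two dim speckles give the intensity-threshold step a dim
        # population to discard (without one it clips near-equal foci)
        centers = [(3.17, 3.23), (9.43, 3.11), (15.27, 3.33), (6.33, 9.87), (12.71, 10.23)]
        img = gaussians(centers, [10.0] * 5, size_um=(18.0, 14.0))
        img += gaussians([(4.91, 11.87), (16.13, 8.41)], [1.5, 1.5],
                         size_um=(18.0, 14.0), sigma=0.1)
        fs = detect_foci(img, pixel_size=0.2)
        assert fs.count == 5
        for cx, cy in centers:
            assert np.min(np.hypot(fs.positions[:, 0] - cx, fs.positions[:, 1] - cy)) < 0.3

    def test_two_gaussians_below_merge_radius_become_one(self):
        img = gaussians([(8.03, 8.05), (8.83, 8.05)], [10.0, 10.0], size_um=(16.0, 16.0))
        fs = detect_foci(img, pixel_size=0.2)
        assert fs.count == 1

    def test_dim_focus_discarded_by_intensity_threshold(self):
        centers = [(3.17, 3.23), (9.43, 3.11), (15.27, 3.33), (9.33, 10.23)]
        img = gaussians(centers, [10.0, 10.0, 10.0, 1.0], size_um=(18.0, 14.0))
        fs = detect_foci(img, pixel_size=0.2)
        assert fs.count == 3
        assert np.min(np.hypot(fs.positions[:, 0] - 9.33, fs.positions[:, 1] - 10.23)) > 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_literal_brute_force_oracle_on_128px_images(self, seed):
        frame, _ = synth_foci_image(
            10, image_size_um=(33.28, 33.28), pixel_size=0.26,
            quantize=False, seed=seed,
        )
        img = frame.intensity
        assert img.shape == (128, 128)
        fs = detect_foci(img, pixel_size=0.26)
        oracle = brute_force_detect(img, ps=0.26)
        assert fs.count == oracle.shape[0]
        got = sorted(map(tuple, np.round(fs.positions, 9)))
        want = sorted(map(tuple, np.round(oracle, 9)))
        assert got == want

    def test_invariant_under_affine_intensity_transform(self):
        frame, _ = synth_foci_image(8, seed=3, quantize=False)
        img = frame.intensity
        a = detect_foci(img, 0.26)
        b = detect_foci(3.7 * img + 55.0, 0.26)
        np.testing.assert_allclose(a.positions, b.positions)

    def test_min_pairwise_separation_at_least_merge_radius(self):
        frame, _ = synth_foci_image(20, seed=4)
        fs = detect_foci(frame.intensity, frame.pixel_size, decrease_epsilon=1.0)
        if fs.count >= 2:
            d = np.hypot(
                fs.positions[:, None, 0] - fs.positions[None, :, 0],
                fs.positions[:, None, 1] - fs.positions[None, :, 1],
            )
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 1.0 - 1e-9

    def test_region_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            detect_foci(np.ones((5, 5)), pixel_size=0.5)


class TestFociDensity:
    def test_arithmetic(self):
        from cortexflow.foci import FociSet

        empty = FociSet(np.empty((0, 2)), np.empty(0), np.empty(0))
        assert foci_density(empty, 351.0) == 0.0
        fifty = FociSet(np.zeros((50, 2)), np.zeros(50), np.zeros(50))
        assert foci_density(fifty, 325.0) == pytest.approx(50 / 325.0)
        with pytest.raises(ValueError):
            foci_density(empty, 0.0)

    def test_well_separated_noiseless_image_recovers_exact_density(self):
        frame, truth = synth_foci_image(
            12, noise_sd=0.0, min_separation=3.0, seed=5, quantize=False,
        )
        fs = detect_foci(frame.intensity, frame.pixel_size)
        area = 27.0 * 13.0
        assert foci_density(fs, area) == pytest.approx(truth.foci_density_true)

    def test_size_density_anticorrelation_across_spacing_series(self):
        """Lattices of increasing spacing: S grows while rho falls."""
        from scipy.stats import spearmanr

        sizes, densities = [], []
        for spacing in (3.0, 4.0, 5.0, 6.0):
            pts = [
                (x, y)
                for x in np.arange(2.0, 24.0, spacing)
                for y in np.arange(2.0, 12.0, spacing)
            ]
            img = gaussians(pts, [10.0] * len(pts), size_um=(26.0, 13.0), ps=0.2)
            radii, prof = radial_average(spatial_autocorrelation(img), 0.2)
            S = foci_size(radii, prof)
            assert S is not None
            sizes.append(S)
            densities.append(len(pts) / (26.0 * 13.0))
        assert spearmanr(sizes, densities).statistic < 0
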