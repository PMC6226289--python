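import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexflow.flow import (
    FlowSummary,
    chiral_counter_velocity,
    condition_histogram,
    correlation_report,
    mean_ap_velocity,
    time_averaged_profile,
    wilcoxon_compare,
)
from cortexflow.geometry import BinnedProfile


def profile_from(vx=None, vy=None, n_bins=18, centers=None):
    centers = centers if centers is not None else np.arange(n_bins) * 3.0 + 1.5
    vx = np.zeros(n_bins) if vx is None else np.asarray(vx, float)
    vy = np.zeros(n_bins) if vy is None else np.asarray(vy, float)
    nan = np.full(n_bins, np.nan)
    return BinnedProfile(centers, np.ones(n_bins), vx, vy, nan, nan, nan, np.ones(n_bins))


class TestFrameStatistics:
    def test_posterior_mean_uniform_and_arithmetic(self, geom):
        vx = np.zeros(18)
        vx[12:16] = 1.0
        assert mean_ap_velocity(profile_from(vx=vx), geom) == pytest.approx(1.0)
        vx[12:16] = [0, 2, 4, 6]
        assert mean_ap_velocity(profile_from(vx=vx), geom) == pytest.approx(3.0)

    def test_posterior_mean_matches_brute_force(self, geom, rng):
        vx = rng.normal(size=18)
        expected = np.mean([vx[b - 1] for b in (13, 14, 15, 16)])
        assert mean_ap_velocity(profile_from(vx=vx), geom) == pytest.approx(expected)

    def test_chiral_velocity_cancels_uniform_vy(self, geom):
        assert chiral_counter_velocity(profile_from(vy=np.full(18, 5.0)), geom) == 0.0

    def test_chiral_velocity_posterior_minus_anterior(self, geom):
        vy = np.zeros(18)
        vy[12:16] = 1.0
        vy[2:6] = -1.0
        assert chiral_counter_velocity(profile_from(vy=vy), geom) == pytest.approx(2.0)

    def test_chiral_velocity_matches_brute_force(self, geom, rng):
        vy = rng.normal(size=18)
        expected = np.mean(vy[[12, 13, 14, 15]]) - np.mean(vy[[2, 3, 4, 5]])
        assert chiral_counter_velocity(profile_from(vy=vy), geom) == pytest.approx(expected)

    def test_chiral_velocity_antisymmetric_under_region_swap(self, geom, rng):
        from cortexflow.geometry import EmbryoGeometry

        swapped = EmbryoGeometry(
            ap_extent=geom.ap_extent,
            y_mid=geom.y_mid,
            posterior_bins=geom.anterior_bins,
            anterior_bins=geom.posterior_bins,
        )
        vy = rng.normal(size=18)
        p = profile_from(vy=vy)
        assert chiral_counter_velocity(p, geom) == pytest.approx(
            -chiral_counter_velocity(p, swapped)
        )

    def test_chiral_velocity_invariant_to_constant_vy_offset(self, geom, rng):
        vy = rng.normal(size=18)
        a = chiral_counter_velocity(profile_from(vy=vy), geom)
        b = chiral_counter_velocity(profile_from(vy=vy + 7.3), geom)
        assert a == pytest.approx(b)

    def test_all_missing_posterior_gives_nan(self, geom):
        p = profile_from()
        p.missing[:] = True
        assert np.isnan(mean_ap_velocity(p, geom))


class TestConditionPooling:
    def test_single_embryo_mean(self):
        s = FlowSummary("c", "e0", [1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        h = condition_histogram([s], "vx")
        assert h.mean == pytest.approx(2.0)

    def test_all_zero_embryos(self):
        ss = [FlowSummary("c", f"e{i}", np.zeros(5), np.zeros(5)) for i in range(2)]
        h = condition_histogram(ss, "vx")
        assert h.mean == 0.0 and h.sem == 0.0

    def test_pooled_mean_matches_brute_force(self, rng):
        frames = [rng.normal(size=7), rng.normal(size=4)]
        ss = [FlowSummary("c", f"e{i}", f, f) for i, f in enumerate(frames)]
        h = condition_histogram(ss, "vx")
        pooled = np.concatenate(frames)
        assert h.mean == pytest.approx(pooled.mean())
        assert h.sem == pytest.approx(pooled.std(ddof=1) / np.sqrt(pooled.size))

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_histogram([], "vx")


def exact_ranksum_oracle(a, b):
    """Literal exhaustive two-sided permutation p for the rank-sum statistic,
    with midranks computed by hand."""
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    mu = n_a * (n + 1) / 2.0
    w_obs = sum(ranks[:n_a])
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = sum(ranks[i] for i in combo)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestWilcoxon:
    def test_identical_samples_not_significant(self):
        p, sig = wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0) and not sig

    def test_separated_samples_match_enumeration(self):
        p, _ = wilcoxon_compare([1, 2, 3], [10, 11, 12], confidence=0.95)
        assert p == pytest.approx(2 / 20)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 7, size=2)
        a = rng.integers(0, 6, n_a).astype(float)  # integer data forces ties
        b = rng.integers(0, 6, n_b).astype(float)
        p, _ = wilcoxon_compare(a, b)
        assert p == pytest.approx(exact_ranksum_oracle(a, b), abs=1e-12)

    def test_permutation_invariance_under_shuffle(self, rng):
        a = rng.normal(size=5)
        p1, _ = wilcoxon_compare(a, a[::-1])
        assert p1 == pytest.approx(1.0)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(loc=2.0, size=60)
        p, sig = wilcoxon_compare(a, b, confidence=0.99)
        assert p < 0.01 and sig

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1.0])

    @given(
        a=st.lists(st.integers(0, 9), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 9), min_size=2, max_size=6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_p_value_symmetric_in_samples_and_valid(self, a, b):
        pa, _ = wilcoxon_compare(np.array(a, float), np.array(b, float))
        pb, _ = wilcoxon_compare(np.array(b, float), np.array(a, float))
        assert 0.0 < pa <= 1.0
        assert pa == pytest.approx(pb, abs=1e-12)


class TestTimeAveragedProfile:
    def test_single_embryo_constant_profile(self):
        p = profile_from(vx=np.arange(18.0))
        out = time_averaged_profile([[p, p, p]])
        np.testing.assert_allclose(out.vx, p.vx)
        assert np.all(np.isnan(out.sem_vx))

    def test_two_embryos_mean_and_sem(self):
        a = profile_from(vx=np.full(18, 1.0))
        b = profile_from(vx=np.full(18, 3.0))
        out = time_averaged_profile([[a], [b]])
        assert np.allclose(out.vx, 2.0)
        assert np.allclose(out.sem_vx, 1.0)

    def test_matches_brute_force_two_stage_average(self, rng):
        stacks = [
            [profile_from(vx=rng.normal(size=18)) for _ in range(3)],
            [profile_from(vx=rng.normal(size=18)) for _ in range(5)],
        ]
        out = time_averaged_profile(stacks)
        embryo_means = np.stack(
            [np.mean([p.vx for p in frames], axis=0) for frames in stacks]
        )
        np.testing.assert_allclose(out.vx, embryo_means.mean(axis=0))

    def test_geometry_mismatch_rejected(self):
        a = profile_from()
        b = profile_from(centers=np.arange(18) * 2.0 + 1.0)
        with pytest.raises(ValueError):
            time_averaged_profile([[a], [b]])


class TestCorrelationReport:
    def test_perfect_linear_correlations(self):
        df = pd.DataFrame(
            {
                "vx_mean": [1.0, 2.0, 3.0, 4.0],
                "vc_mean": [2.0, 4.0, 6.0, 8.0],
                "S": [-1.0, -2.0, -3.0, -4.0],
                "rho": [0.1, 0.2, 0.3, 0.4],
            }
        )
        rep = correlation_report(df).set_index(["quantity_a", "quantity_b"])
        assert rep.loc[("vx_mean", "vc_mean"), "R"] == pytest.approx(1.0)
        assert rep.loc[("vx_mean", "S"), "R"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        df = pd.DataFrame({"vx_mean": x, "vc_mean": y})
        rep = correlation_report(df, pairs=(("vx_mean", "vc_mean"),))
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert rep["R"].iloc[0] == pytest.approx(r)

    def test_too_few_complete_pairs_rejected(self):
        df = pd.DataFrame({"vx_mean": [1.0, 2.0], "vc_mean": [1.0, np.nan]})
        with pytest.raises(ValueError):
            correlation_report(df, pairs=(("vx_mean", "vc_mean"),))
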