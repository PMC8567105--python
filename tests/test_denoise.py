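"""MI-NLTV denoiser: entropies, joint histograms, weight maps, the weighted
TV objective/gradient pair and the adaptive descent."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minltv.core import Volume
from minltv.denoise import (
    DenoiseParams,
    JointHistogram,
    build_joint_histogram,
    compute_weight_map,
    denoise,
    entropy,
    mutual_information,
    nlm_weight_map,
    statistical_measure,
    tv_gradient,
    tv_objective,
    _measure_map,
)


class TestEntropy:
    @pytest.mark.parametrize(
        "marginal, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 2.0),
            ([1.0, 0.0, 0.0, 0.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_known_values(self, marginal, expected):
        assert entropy(np.array(marginal)) == pytest.approx(expected, abs=1e-12)

    def test_counts_normalized_internally(self):
        assert entropy(np.array([2, 2, 2, 2])) == pytest.approx(2.0)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([]))
        with pytest.raises(ValueError):
            entropy(np.zeros(4))


class TestMutualInformation:
    def test_diagonal_counts_give_marginal_entropy(self):
        h = JointHistogram(np.diag([3.0, 1.0, 2.0, 2.0]))
        assert mutual_information(h) == pytest.approx(entropy(h.marginal_a), abs=1e-12)

    def test_independent_counts_give_zero(self):
        a = np.array([0.5, 0.3, 0.2])
        b = np.array([0.25, 0.75])
        h = JointHistogram(np.outer(a, b) * 40)
        assert mutual_information(h) == pytest.approx(0.0, abs=1e-12)

    def test_2x2_scalar_oracle(self):
        """counts [[2,1],[1,2]] evaluated by direct plug-in of the entropy
        definitions."""
        h = JointHistogram(np.array([[2.0, 1.0], [1.0, 2.0]]))
        # oracle: H(A)=H(B)=1 bit; H(AB) = -2*(2/6)log2(2/6) - 2*(1/6)log2(1/6)
        h_ab = -2 * (2 / 6) * np.log2(2 / 6) - 2 * (1 / 6) * np.log2(1 / 6)
        expect = 1.0 + 1.0 - h_ab
        assert mutual_information(h) == pytest.approx(expect, abs=1e-12)
        assert statistical_measure(h) == pytest.approx(expect / 1.0, abs=1e-12)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_mi_identities_random_histograms(self, seed):
        """0 <= MI <= min(H_A, H_B); symmetric under transposition;
        M in [0, 1]."""
        rng = np.random.default_rng(seed)
        b = int(rng.integers(2, 9))
        counts = rng.integers(0, 20, size=(b, b)).astype(float)
        if counts.sum() == 0:
            counts[0, 0] = 1.0
        h = JointHistogram(counts)
        mi = mutual_information(h)
        assert 0.0 <= mi <= min(entropy(h.marginal_a + 1e-300),
                                entropy(h.marginal_b + 1e-300)) + 1e-12
        assert mi == pytest.approx(mutual_information(JointHistogram(counts.T)),
                                   abs=1e-12)
        assert 0.0 <= statistical_measure(h) <= 1.0


class TestJointHistogram:
    def test_constant_slice_all_pairs_in_origin_bin(self):
        p = DenoiseParams(a=1, search_radius=1, bins=2)
        h = build_joint_histogram(np.ones((8, 8)), (4, 4), p)
        assert h.n == 72  # (2a+1)^2 * ((2s+1)^2 - 1) = 9 * 8
        assert h.counts[0, 0] == 72

    def test_identical_translate_limit_gives_m_one(self):
        """When every moving patch matches the stationary patch bin for
        bin, the histogram is diagonal and M = MI/H_A = 1."""
        stat = np.array([0, 1, 2, 3, 0, 1, 2, 3, 0])
        counts = np.zeros((8, 8))
        np.add.at(counts, (stat, stat), 1.0)
        h = JointHistogram(counts)
        assert mutual_information(h) == pytest.approx(entropy(h.marginal_a), abs=1e-12)
        assert statistical_measure(h) == pytest.approx(1.0, abs=1e-12)

    def test_structured_stripes_beat_noise(self):
        """A 4-level stripe pattern keeps every displaced patch in a
        deterministic relation to the stationary one, so the pooled M is
        far above that of an unstructured noise slice."""
        p = DenoiseParams(a=1, search_radius=1, bins=8)
        yy = np.arange(16)
        stripes = np.tile((yy % 4).astype(float)[:, None], (1, 16))
        m_stripes = statistical_measure(build_joint_histogram(stripes, (8, 8), p))
        rng = np.random.default_rng(0)
        noise = rng.uniform(0, 1, (16, 16))
        m_noise = statistical_measure(build_joint_histogram(noise, (8, 8), p))
        assert m_stripes > 0.1
        assert m_stripes > 3 * m_noise

    def test_matches_bruteforce_loop_oracle(self):
        """Histogram counts vs a double-loop reimplementation."""
        rng = np.random.default_rng(5)
        p = DenoiseParams(a=1, search_radius=2, bins=6)
        sl = rng.uniform(0, 1, (16, 16))
        h = build_joint_histogram(sl, (8, 7), p)

        lo, hi = sl.min(), sl.max()
        pad = p.a + p.search_radius
        padded = np.pad(sl, pad, mode="reflect")
        binned = np.clip(
            np.floor((padded - lo) / (hi - lo) * p.bins).astype(int), 0, p.bins - 1
        )
        counts = np.zeros((p.bins, p.bins))
        r0, c0 = 8 + pad, 7 + pad
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                if dr == 0 and dc == 0:
                    continue
                for pr in range(-1, 2):
                    for pc in range(-1, 2):
                        bi = binned[r0 + pr, c0 + pc]
                        bj = binned[r0 + dr + pr, c0 + dc + pc]
                        counts[bi, bj] += 1
        np.testing.assert_array_equal(h.counts, counts)

    def test_flat_slice_is_valid(self):
        p = DenoiseParams(a=1, search_radius=1, bins=4)
        h = build_joint_histogram(np.full((8, 8), 3.3), (4, 4), p)
        assert h.counts[0, 0] == h.n

    def test_featureless_patch_measure_is_zero(self):
        h = JointHistogram(np.array([[10.0, 0.0], [0.0, 0.0]]))
        assert statistical_measure(h) == 0.0


class TestWeightMaps:
    def test_zero_measure_gives_unit_weight(self):
        p = DenoiseParams()
        sl = np.full((30, 30), 1.0)  # constant slice -> M = 0 everywhere
        wm = compute_weight_map(sl, p, tau=1.0)
        np.testing.assert_allclose(wm.measure, 0.0, atol=1e-12)
        np.testing.assert_allclose(wm.values, 1.0, atol=1e-12)

    def test_spatial_factor_reference_point(self):
        """V = tau, rho = 10, M = 1 composes to exp(-1)."""
        p = DenoiseParams(rho=10.0)
        from minltv.denoise import _compose_weights

        w = _compose_weights(np.array([[1.0]]), np.array([[1.0]]), tau=1.0, params=p)
        assert w[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_mi_map_matches_cleanroom_oracle(self):
        """Full weight map vs an independent per-pixel computation built
        from build_joint_histogram + statistical_measure + Eq. composition."""
        rng = np.random.default_rng(11)
        p = DenoiseParams(a=1, search_radius=2, bins=8, rho=3.0)
        sl = rng.uniform(0.5, 2.0, (12, 12))
        tau = 1.5
        wm = compute_weight_map(sl, p, tau=tau)
        for r, c in [(0, 0), (3, 7), (11, 11), (6, 2)]:
            m = statistical_measure(build_joint_histogram(sl, (r, c), p))
            w = np.exp(-((max(sl[r, c], 0) / tau) ** 3.0) * m)
            assert wm.measure[r, c] == pytest.approx(m, abs=1e-12)
            assert wm.values[r, c] == pytest.approx(w, rel=1e-12)

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(2)
        sl = rng.uniform(0, 1, (20, 20))
        wm = compute_weight_map(sl, DenoiseParams(a=1, search_radius=2, bins=16))
        assert np.all(wm.values > 0) and np.all(wm.values <= 1)
        assert np.all(wm.measure >= 0) and np.all(wm.measure <= 1)

    def test_pure_noise_slice_is_mostly_smoothing(self):
        """On flat + noise the weights stay near one (smoothing state)."""
        rng = np.random.default_rng(4)
        sl = 1.0 + 0.05 * rng.normal(size=(32, 32))
        wm = compute_weight_map(sl, DenoiseParams(a=2, search_radius=5, bins=32))
        assert wm.values.mean() >= 0.9

    def test_nlm_self_similar_window_gives_m_one(self):
        p = DenoiseParams(weight_mode="nlm", a=1, search_radius=2, nlm_h=0.5)
        sl = np.zeros((12, 12))  # all patches identical -> ssd = 0 -> M = 1
        wm = nlm_weight_map(sl, p, tau=1.0)
        np.testing.assert_allclose(wm.measure, 1.0, atol=1e-12)

    def test_nlm_large_bandwidth_limit(self):
        rng = np.random.default_rng(6)
        sl = rng.uniform(0, 1, (10, 10))
        p = DenoiseParams(weight_mode="nlm", a=1, search_radius=1, nlm_h=1e6)
        wm = nlm_weight_map(sl, p, tau=1.0)
        np.testing.assert_allclose(wm.measure, 1.0, atol=1e-6)

    def test_nlm_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        sl = rng.uniform(0, 1, (10, 10))
        p = DenoiseParams(weight_mode="nlm", a=1, search_radius=1, nlm_h=0.3)
        wm = nlm_weight_map(sl, p, tau=1.0)
        pad = 2
        padded = np.pad(sl, pad, mode="reflect")
        h2 = 9 * 0.3**2
        r, c = 4, 6
        acc = []
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                ssd = 0.0
                for pr in range(-1, 2):
                    for pc in range(-1, 2):
                        d = padded[r + pad + pr, c + pad + pc] - padded[
                            r + pad + dr + pr, c + pad + dc + pc
                        ]
                        ssd += d * d
                acc.append(np.exp(-ssd / h2))
        assert wm.measure[r, c] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_tau_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            compute_weight_map(np.zeros((8, 8)), DenoiseParams(a=1, search_radius=1))


class TestTvObjectiveGradient:
    def test_constant_slice_objective_is_n_eps(self):
        v = np.full((6, 6), 2.0)
        w = np.ones((6, 6))
        assert tv_objective(v, w, eps=0.01) == pytest.approx(36 * 0.01, rel=1e-12)

    def test_hand_arithmetic_2x2(self):
        v = np.array([[0.0, 1.0], [0.0, 1.0]])
        w = np.ones((2, 2))
        # backward diffs: D(0,0)=0, D(0,1)=1, D(1,0)=0, D(1,1)=1
        assert tv_objective(v, w, eps=0.0) == pytest.approx(2.0, abs=1e-12)

    def test_random_slice_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(8, 8))
        w = rng.uniform(0.1, 1, (8, 8))
        eps = 0.05
        acc = 0.0
        for r in range(8):
            for c in range(8):
                dr = v[r, c] - v[r - 1, c] if r > 0 else 0.0
                dc = v[r, c] - v[r, c - 1] if c > 0 else 0.0
                acc += w[r, c] * np.sqrt(dr * dr + dc * dc + eps * eps)
        assert tv_objective(v, w, eps) == pytest.approx(acc, rel=1e-12)

    def test_constant_slice_zero_gradient(self):
        g, norm = tv_gradient(np.full((5, 5), 3.0), np.ones((5, 5)), eps=1e-3)
        np.testing.assert_allclose(g, 0.0, atol=1e-15)
        assert norm == pytest.approx(0.0, abs=1e-15)

    def test_gradient_matches_central_differences(self):
        """The single most important correctness gate: analytic gradient
        vs numerical differentiation of the objective, 50 random slices."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            v = rng.normal(size=(12, 12))
            w = rng.uniform(0.05, 1.0, (12, 12))
            eps = 10 ** rng.uniform(-3, -1)
            g, norm = tv_gradient(v, w, eps)
            h = 1e-6 * (v.max() - v.min())
            num = np.zeros_like(v)
            for r in range(12):
                for c in range(12):
                    vp = v.copy()
                    vp[r, c] += h
                    vm = v.copy()
                    vm[r, c] -= h
                    num[r, c] = (tv_objective(vp, w, eps) - tv_objective(vm, w, eps)) / (2 * h)
            scale = np.abs(num).max()
            assert np.abs(g - num).max() / scale <= 1e-4
            assert norm == pytest.approx(np.sqrt((g**2).sum()), rel=1e-12)

    def test_bump_sign_pattern(self):
        """A single bump pulls itself down and its right/down neighbours up."""
        v = np.zeros((7, 7))
        v[3, 3] = 1.0
        g, _ = tv_gradient(v, np.ones((7, 7)), eps=1e-6)
        assert g[3, 3] > 0
        assert g[4, 3] < 0 and g[3, 4] < 0

    def test_shift_covariance(self):
        """Adding a constant changes neither objective differences nor the
        gradient (the TV term sees only differences)."""
        rng = np.random.default_rng(10)
        v = rng.normal(size=(9, 9))
        w = rng.uniform(0.1, 1, (9, 9))
        g1, n1 = tv_gradient(v, w, 0.01)
        g2, n2 = tv_gradient(v + 5.0, w, 0.01)
        np.testing.assert_allclose(g1, g2, atol=1e-12)
        assert n1 == pytest.approx(n2, rel=1e-12)


def noisy_disk_volume(seed, n=64, nz=1):
    rng = np.random.default_rng(seed)
    x, y = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2)
    disk = np.where(x**2 + y**2 < (0.4 * n) ** 2, 0.02, 0.0)
    noisy = disk + 0.002 * rng.normal(size=disk.shape) * (disk > 0)
    data = np.repeat(noisy[None], nz, axis=0)
    return Volume(data=data, spacing=(1, 1, 1), origin=(0, 0, 0)), (
        x**2 + y**2 < (0.3 * n) ** 2
    )


class TestDenoise:
    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((2, 16, 16), 0.02), (1, 1, 1), (0, 0, 0))
        out, states = denoise(vol, DenoiseParams(a=1, search_radius=2, iterations=5))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_noise_strictly_reduced(self, seed):
        vol, interior = noisy_disk_volume(seed)
        out, _ = denoise(vol, DenoiseParams())
        assert out.data[0][interior].std() < vol.data[0][interior].std()
        assert np.all(np.isfinite(out.data))

    def test_objective_minimum_at_final_accepted_iterate(self):
        vol, _ = noisy_disk_volume(1)
        _, states = denoise(vol, DenoiseParams())
        r = states[0].r_history
        assert r[-1] < r[0]
        assert int(np.argmin(r)) == len(r) - 1

    def test_gamma_never_increases(self):
        vol, _ = noisy_disk_volume(2)
        _, states = denoise(vol, DenoiseParams())
        gh = states[0].gamma_history
        assert all(b <= a for a, b in zip(gh, gh[1:]))

    def test_hu_volume_rejected(self):
        vol = Volume(np.zeros((1, 8, 8)), (1, 1, 1), (0, 0, 0), unit="HU")
        with pytest.raises(ValueError, match="mu_mm"):
            denoise(vol)

    def test_nlm_pathway_parity(self):
        """weight_mode='nlm' runs the identical descent machinery end to
        end and also reduces noise."""
        vol, interior = noisy_disk_volume(3)
        out, states = denoise(vol, DenoiseParams(weight_mode="nlm"))
        assert out.data[0][interior].std() < vol.data[0][interior].std()
        assert len(states[0].r_history) == 21

    def test_per_patch_aggregate_runs(self):
        """The per-patch-averaged MI variant is consistent with pooled on a
        tiny slice (both bounded, both in [0,1])."""
        rng = np.random.default_rng(3)
        sl = rng.uniform(0, 1, (6, 6))
        p = DenoiseParams(a=1, search_radius=1, bins=4, aggregate="per_patch")
        m = _measure_map(sl, p)
        assert np.all((m >= 0) & (m <= 1))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DenoiseParams(a=0)
        with pytest.raises(ValueError):
            DenoiseParams(search_radius=1, a=2)
        with pytest.raises(ValueError):
            DenoiseParams(r_red=1.0)
        with pytest.raises(ValueError):
            DenoiseParams(tau_percentile=100.0)
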