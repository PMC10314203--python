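"""Bispectrum, RABS/rabs, the J0 transform kernel and mirror maps."""

import numpy as np
import pytest

import motinv as mi
from motinv._conventions import signed_angle
from motinv.patterns import GridSignal, mirror_signal, rot90_signal, translate_signal


@pytest.fixture(scope="module")
def gauss5_signal():
    rng = np.random.default_rng(0)
    pat = mi.PointPattern(rng.normal(0, 1.2, (5, 2)), R=0.5)
    return pat, mi.rasterize(pat, 64, 0.25)


class TestBispectrum:
    def test_translation_invariance_off_grid(self, gauss5_signal):
        _, sig = gauss5_signal
        F0 = mi.fourier_transform(sig)
        F1 = mi.fourier_transform(translate_signal(sig, (5, -3)))
        k = np.array([0.7331, -0.411])
        q = np.array([-0.211, 0.9314])
        b0, b1 = mi.bispectrum(F0, k, q), mi.bispectrum(F1, k, q)
        assert abs(b1 - b0) < 1e-8 * abs(b0)

    def test_single_gaussian_is_real_positive_wilson_product(self):
        pat = mi.PointPattern([[0.0, 0.0]], R=1.0)
        F = mi.fourier_transform_padded(mi.rasterize(pat, 64, 0.25), 4)
        k = np.array([0.51, -0.32])
        q = np.array([-0.15, 0.69])
        b = mi.bispectrum(F, k, q)
        pred = np.exp(
            -(k @ k + q @ q + (k + q) @ (k + q)) / 2.0
        )
        assert abs(b.imag) < 1e-10
        assert b.real > 0
        assert b.real == pytest.approx(pred, rel=0.02)

    def test_on_grid_single_gaussian_is_exact(self):
        pat = mi.PointPattern([[0.0, 0.0]], R=1.0)
        F = mi.fourier_transform(mi.rasterize(pat, 64, 0.25))
        dk = F.kspacing
        k = np.array([2 * dk, -dk])
        q = np.array([-dk, 3 * dk])
        pred = np.exp(-(k @ k + q @ q + (k + q) @ (k + q)) / 2.0)
        assert mi.bispectrum(F, k, q).real == pytest.approx(pred, rel=1e-6)

    def test_zero_wavevectors_give_total_mass_cubed(self, gauss5_signal):
        _, sig = gauss5_signal
        F = mi.fourier_transform(sig)
        total = sig.values.sum() * sig.spacing**2
        b = mi.bispectrum(F, np.zeros(2), np.zeros(2))
        assert b.real == pytest.approx(total**3, rel=1e-10)

    def test_out_of_band_rejected(self, gauss5_signal):
        _, sig = gauss5_signal
        F = mi.fourier_transform(sig)
        big = np.array([0.9 * np.pi / sig.spacing, 0.0])
        with pytest.raises(ValueError, match="band"):
            mi.bispectrum(F, big, big)


class TestRabsFourier:
    def test_motion_invariance_rot90_plus_translation(self, gauss5_signal):
        _, sig = gauss5_signal
        ks = np.linspace(0.3, 1.5, 6)
        ths = mi.theta_grid(8)
        rg0 = mi.rabs_fourier(mi.fourier_transform(sig), ks, ks, ths, M=64)
        moved = translate_signal(rot90_signal(sig), (4, 7))
        rg1 = mi.rabs_fourier(mi.fourier_transform(moved), ks, ks, ths, M=64)
        err = np.abs(rg1.values - rg0.values).max() / np.abs(rg0.values).max()
        assert err < 1e-6
        assert rg0.meta["max_imag_ratio"] < 1e-8

    def test_ring_pattern_peaks_at_equilateral_triple(self):
        R = 1.6
        ring = mi.ring_pattern(R, 128, 1.0)
        F = mi.fourier_transform_padded(ring, 4)
        ks = np.linspace(0.35, 0.95, 9)
        ths = mi.theta_grid(12)
        rg = mi.rabs_fourier(F, ks, ks, ths, M=128)
        vals = np.abs(rg.values)
        i, j, t = np.unravel_index(np.argmax(vals), vals.shape)
        k_ring = 1.0 / R
        assert abs(ks[i] - k_ring) <= 0.5 * (ks[1] - ks[0]) + 1e-9
        assert abs(ks[j] - k_ring) <= 0.5 * (ks[1] - ks[0]) + 1e-9
        assert abs(abs(ths[t]) - 2 * np.pi / 3) < 1e-9
        # bins whose wavevector triple is off-resonant (fewer than two of
        # k, q, |k+q| within the ring's spectral width, and k+q away from 0)
        K, Q, T = np.meshgrid(ks, ks, ths, indexing="ij")
        third = np.sqrt(K**2 + Q**2 + 2 * K * Q * np.cos(T))
        width = 2 * 2 * np.pi / 128
        near = (
            (np.abs(K - k_ring) < width).astype(int)
            + (np.abs(Q - k_ring) < width).astype(int)
            + (np.abs(third - k_ring) < width).astype(int)
        )
        off_resonant = (near < 2) & (third > 3 * 2 * np.pi / 128)
        assert vals[off_resonant].max() <= 0.10 * vals.max()

    def test_mirror_image_equals_mirror_map(self, gauss5_signal):
        _, sig = gauss5_signal
        ks = np.linspace(0.3, 1.5, 6)
        ths = mi.theta_grid(8)
        rg0 = mi.rabs_fourier(mi.fourier_transform(sig), ks, ks, ths, M=64)
        rgm = mi.rabs_fourier(
            mi.fourier_transform(mirror_signal(sig, 1)), ks, ks, ths, M=64
        )
        scale = np.abs(rg0.values).max()
        assert np.abs(rgm.values - mi.mirror_map(rg0).values).max() < 1e-6 * scale

    def test_swap_symmetry_of_the_two_lengths(self, gauss5_signal):
        # B(k, q) = B(q, k) and the relative angle flips sign
        _, sig = gauss5_signal
        ks = np.linspace(0.4, 1.2, 5)
        ths = mi.theta_grid(8)
        rg = mi.rabs_fourier(mi.fourier_transform(sig), ks, ks, ths, M=64)
        swapped = mi.mirror_map(rg).values.transpose(1, 0, 2)
        assert np.abs(swapped - rg.values).max() < 1e-9 * np.abs(rg.values).max()


class TestRabsReal:
    def test_matches_brute_force_triple_sum_8x8(self):
        rng = np.random.default_rng(3)
        f = GridSignal(rng.random((8, 8)), 0.5)

        def brute(rv, sv):
            n = 8
            total = 0.0
            for t0 in range(n):
                for t1 in range(n):
                    total += (
                        f.values[t0, t1]
                        * f.values[(t0 + rv[0]) % n, (t1 + rv[1]) % n]
                        * f.values[(t0 + sv[0]) % n, (t1 + sv[1]) % n]
                    )
            return total * 0.5**2

        for rv, sv in (((1, 2), (3, -1)), ((0, 0), (2, 2)), ((-3, 1), (1, 4))):
            got = mi.three_point_function(
                f, np.array(rv) * 0.5, np.array(sv) * 0.5
            )
            assert got == pytest.approx(brute(rv, sv), rel=1e-8)

    def test_translation_invariance(self, three_atom):
        sig = mi.rasterize(three_atom, 64, 0.3125)
        rr = np.arange(0.0, 6.01, 0.5)
        ths = mi.theta_grid(16)
        rg0 = mi.rabs_real(sig, rr, rr, ths, M=32)
        rg1 = mi.rabs_real(translate_signal(sig, (3, -5)), rr, rr, ths, M=32)
        err = np.abs(rg1.values - rg0.values).max() / np.abs(rg0.values).max()
        assert err < 1e-10

    def test_punctate_pattern_mass_sits_at_its_triangles(self):
        import itertools

        pat = mi.PointPattern([[-1.5, 0.0], [1.5, 0.0], [0.0, 2.0]], R=0.25)
        sig = mi.rasterize(pat, 96, 0.25)
        rr = np.arange(0.0, 5.51, 0.25)
        ths = mi.theta_grid(32)
        rg = mi.rabs_real(sig, rr, rr, ths, M=32)
        # mask the self-term ridges (r ~ 0, s ~ 0, or r ~ s with theta ~ 0,
        # each of width ~ a few R); what remains is the triangle resonance
        Rv, Sv, Tv = np.meshgrid(rr, rr, ths, indexing="ij")
        self_ridge = (
            (Rv < 1.0)
            | (Sv < 1.0)
            | ((np.abs(Rv - Sv) < 1.0) & (np.abs(Tv) < 0.6))
        )
        masked = np.where(self_ridge, -np.inf, rg.values)
        am = np.unravel_index(np.argmax(masked), masked.shape)
        # expected cells: ordered displacement pairs from a common vertex
        cells = set()
        for i, j, k in itertools.permutations(range(3), 3):
            rvec = pat.centers[j] - pat.centers[i]
            svec = pat.centers[k] - pat.centers[i]
            cells.add(
                (
                    int(np.argmin(np.abs(rr - np.linalg.norm(rvec)))),
                    int(np.argmin(np.abs(rr - np.linalg.norm(svec)))),
                    int(np.argmin(np.abs(ths - float(signed_angle(svec, rvec))))),
                )
            )
        nt = len(ths)
        assert any(
            abs(am[0] - c[0]) <= 1
            and abs(am[1] - c[1]) <= 1
            and min(abs(am[2] - c[2]), nt - abs(am[2] - c[2])) <= 1
            for c in cells
        )
        # and every expected triangle cell carries appreciable mass
        for c in cells:
            assert rg.values[c] > 0.5 * masked[am]

    def test_incommensurate_theta_rejected(self, three_atom):
        sig = mi.rasterize(three_atom, 32, 0.625)
        with pytest.raises(ValueError, match="2\\*pi/M"):
            mi.rabs_real(sig, np.arange(3.0), np.arange(3.0), np.array([0.1]), M=16)


class TestRabsKernel:
    def test_mirror_flip_equivalence(self):
        k, q, r, s = 0.8, 1.1, 2.0, 3.1
        th_qk, th_sr = 0.7, -1.9
        a = mi.rabs_kernel(k, q, -th_qk, r, s, th_sr)
        b = mi.rabs_kernel(k, q, th_qk, r, s, -th_sr)
        assert a == pytest.approx(b, rel=1e-14)

    def test_degenerate_lengths_lose_angle_dependence(self):
        k, r, s = 0.9, 1.7, 2.3
        vals = [
            mi.rabs_kernel(k, 0.0, th, r, s, 0.3) for th in (-2.0, 0.0, 1.4)
        ]
        from scipy.special import j0

        assert np.allclose(vals, j0(k * r), atol=1e-14)

    def test_monte_carlo_joint_rotation_average(self):
        # kernel = < cos(k.Rr + q.Rs) > over joint rotations
        rng = np.random.default_rng(7)
        k_len, q_len, th_qk = 0.9, 1.3, 0.8
        r_len, s_len, th_sr = 1.8, 2.4, -1.1
        kv = k_len * np.array([1.0, 0.0])
        qv = q_len * np.array([np.cos(th_qk), np.sin(th_qk)])
        rv = r_len * np.array([1.0, 0.0])
        sv = s_len * np.array([np.cos(th_sr), np.sin(th_sr)])
        phi = rng.uniform(0, 2 * np.pi, 10**6)
        c, s = np.cos(phi), np.sin(phi)
        rrot = np.stack([c * rv[0] - s * rv[1], s * rv[0] + c * rv[1]], 1)
        srot = np.stack([c * sv[0] - s * sv[1], s * sv[0] + c * sv[1]], 1)
        samples = np.cos(rrot @ kv + srot @ qv)
        se = samples.std() / np.sqrt(len(samples))
        want = mi.rabs_kernel(k_len, q_len, th_qk, r_len, s_len, th_sr)
        assert abs(samples.mean() - want) < 3 * se

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            mi.rabs_kernel(-1.0, 1.0, 0.0, 1.0, 1.0, 0.0)


class TestRealToFourierTransform:
    def test_two_route_consistency(self, three_atom):
        sig = mi.rasterize(three_atom, 64, 0.3125)
        rr = np.arange(0.0, 7.51, 0.2)
        rg_real = mi.rabs_real(sig, rr, rr, mi.theta_grid(48), M=48)
        kv = np.linspace(0.3, 1.5, 5)
        thk = mi.theta_grid(8)
        via_real = mi.rabs_real_to_fourier(rg_real, kv, kv, thk)
        direct = mi.rabs_fourier(
            mi.fourier_transform_padded(sig, 4), kv, kv, thk, M=96
        )
        A, B = direct.values, via_real.values
        mask = np.abs(A) > 0.1 * np.abs(A).max()
        assert (np.abs(A - B)[mask] / np.abs(A)[mask]).max() < 0.05

    def test_zero_input_zero_output(self):
        rr = np.linspace(0.0, 3.0, 8)
        rg = mi.RabsGrid(
            rr, rr, mi.theta_grid(8), np.zeros((8, 8, 8)), "real"
        )
        out = mi.rabs_real_to_fourier(rg, rr[1:], rr[1:], mi.theta_grid(4))
        assert not out.values.any()

    def test_commutes_with_mirror_map(self, three_atom):
        sig = mi.rasterize(three_atom, 64, 0.3125)
        rr = np.arange(0.0, 7.51, 0.4)
        rg_real = mi.rabs_real(sig, rr, rr, mi.theta_grid(24), M=24)
        kv = np.linspace(0.4, 1.2, 4)
        thk = mi.theta_grid(8)
        a = mi.rabs_real_to_fourier(mi.mirror_map(rg_real), kv, kv, thk)
        b = mi.mirror_map(mi.rabs_real_to_fourier(rg_real, kv, kv, thk))
        assert np.abs(a.values - b.values).max() < 1e-9 * np.abs(b.values).max()

    def test_boundary_warning_recorded(self):
        rr = np.linspace(0.0, 2.0, 6)
        vals = np.ones((6, 6, 8))
        rg = mi.RabsGrid(rr, rr, mi.theta_grid(8), vals, "real")
        out = mi.rabs_real_to_fourier(rg, rr[1:3], rr[1:3], mi.theta_grid(4))
        assert out.meta["warnings"]


class TestMirrorMap:
    def test_involution(self, gauss5_signal):
        _, sig = gauss5_signal
        ks = np.linspace(0.4, 1.0, 4)
        ths = mi.theta_grid(10)
        rg = mi.rabs_fourier(mi.fourier_transform(sig), ks, ks, ths, M=32)
        twice = mi.mirror_map(mi.mirror_map(rg))
        assert np.array_equal(twice.values, rg.values)

    def test_achiral_ring_is_mirror_symmetric(self):
        ring = mi.ring_pattern(1.6, 64, 1.0)
        ks = np.linspace(0.4, 0.9, 5)
        ths = mi.theta_grid(8)
        rg = mi.rabs_fourier(mi.fourier_transform(ring), ks, ks, ths, M=64)
        err = np.abs(mi.mirror_map(rg).values - rg.values).max()
        assert err < 1e-8 * np.abs(rg.values).max()

    def test_asymmetric_theta_grid_rejected(self):
        rr = np.linspace(0, 1, 3)
        rg = mi.RabsGrid(
            rr, rr, np.array([0.1, 0.5, 1.0]), np.zeros((3, 3, 3)), "real"
        )
        with pytest.raises(ValueError):
            mi.mirror_map(rg)


class TestMirrorDiscrimination:
    def test_five_point_mirror_pair_rps_same_rabs_differ(self, chiral5):
        sig_a = mi.rasterize(chiral5, 64, 0.25)
        sig_b = mi.rasterize(mi.mirror_pattern(chiral5, 1), 64, 0.25)
        rps_a = mi.rps_from_fourier(mi.fourier_transform(sig_a))
        rps_b = mi.rps_from_fourier(mi.fourier_transform(sig_b))
        assert np.nanmax(np.abs(rps_a.values - rps_b.values)) < 1e-10 * np.nanmax(
            rps_a.values
        )
        ks = np.linspace(0.5, 2.5, 7)
        ths = mi.theta_grid(12)
        rg_a = mi.rabs_fourier(mi.fourier_transform(sig_a), ks, ks, ths, M=64)
        rg_b = mi.rabs_fourier(mi.fourier_transform(sig_b), ks, ks, ths, M=64)
        separation = np.abs(rg_a.values - rg_b.values).max()
        restored = np.abs(rg_a.values - mi.mirror_map(rg_b).values).max()
        assert separation > 10 * restored
        assert separation > 1e-4 * np.abs(rg_a.values).max()
        assert restored < 1e-6 * np.abs(rg_a.values).max()


class TestVanishingRabs:
    def test_odd_order_harmonic_rabs_is_machine_zero(self):
        # for odd m the angular orders 2m + 4Z of the sampled pattern can
        # never sum to zero over a triangle, so even the discretized RABS
        # vanishes identically
        ring = mi.ring_pattern(1.6, 64, 1.0)
        harm = mi.harmonic_pattern(1, 1.6, 64, 1.0)
        ks = np.linspace(0.4, 0.9, 5)
        ths = mi.theta_grid(8)
        peak = np.abs(
            mi.rabs_fourier(mi.fourier_transform(ring), ks, ks, ths, M=64).values
        ).max()
        rg = mi.rabs_fourier(mi.fourier_transform(harm), ks, ks, ths, M=64)
        assert np.abs(rg.values).max() < 1e-12 * peak
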