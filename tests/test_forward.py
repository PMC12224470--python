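"""Forward-model checks: kernel, Legendre projections, SH factorization,
rotational invariants, noise and Watson ODFs.

Independent oracles: closed-form stick integrals, brute-force spherical
quadrature of the convolution, Legendre orthogonality, and Monte-Carlo
sampling of the Watson density.
"""

import numpy as np
import pytest
from scipy.integrate import quad

from smikit import forward as fw
from smikit._sph import fibonacci_hemisphere, random_rotation, real_sh_basis
from smikit.protocol import Protocol, default_protocol


def sphere_quadrature(n_theta=120, n_phi=121):
    """Product quadrature nodes/weights on the unit sphere, total weight 1."""
    x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    st = np.sqrt(1.0 - x**2)
    nodes = np.stack([
        np.outer(st, np.cos(phi)).ravel(),
        np.outer(st, np.sin(phi)).ravel(),
        np.outer(x, np.ones(n_phi)).ravel()], axis=1)
    weights = np.outer(w / 2.0, np.full(n_phi, 1.0 / n_phi)).ravel()
    return nodes, weights


class TestKernelSignal:
    def test_b0_returns_s0(self):
        p = fw.KernelParams(0.3, 2.2, 1.9, 0.5, s0=1.7)
        assert fw.kernel_signal(p, 0.0, 0.3) == pytest.approx(1.7, abs=1e-15)

    def test_isotropic_collapse_independent_of_xi(self):
        p = fw.KernelParams(0.0, 1.0, 1.2, 1.2)
        vals = [fw.kernel_signal(p, 1.5, xi) for xi in (0.0, 0.4, 1.0)]
        assert np.allclose(vals, np.exp(-1.5 * 1.2), atol=1e-15)

    def test_scalar_evaluation(self):
        p = fw.KernelParams(0.5, 2.0, 2.0, 0.7)
        assert fw.kernel_signal(p, 1.0, 1.0) == pytest.approx(
            np.exp(-2.0), rel=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(f=1.2, da=2, depar=2, deperp=0.7),
        dict(f=0.5, da=3.5, depar=2, deperp=0.7),
        dict(f=0.5, da=2, depar=0.5, deperp=0.7),  # deperp > depar
        dict(f=0.8, da=2, depar=2, deperp=0.7, fiso=0.3),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            fw.KernelParams(**bad)

    def test_value_in_unit_interval_scaled_by_s0(self, rng):
        for _ in range(50):
            p = fw.KernelParams(rng.uniform(0, 1), rng.uniform(0, 3),
                                2.5, rng.uniform(0, 2.5), s0=2.0)
            v = fw.kernel_signal(p, rng.uniform(0, 3), rng.uniform(0, 1))
            assert 0.0 < v <= 2.0 + 1e-12


class TestKernelProjection:
    def test_b0_l0_is_s0(self):
        p = fw.KernelParams(0.4, 2, 2, 0.6, s0=1.3)
        assert fw.kernel_projection(p, 0.0, 0) == pytest.approx(1.3, abs=1e-14)

    def test_b0_l2_vanishes(self):
        p = fw.KernelParams(0.4, 2, 2, 0.6)
        assert fw.kernel_projection(p, 0.0, 2) == pytest.approx(0.0, abs=1e-14)

    def test_stick_l0_closed_form(self):
        # pure stick: K_0(b) = sqrt(pi/(4 b Da)) erf(sqrt(b Da))
        p = fw.KernelParams(1.0, 2.0, 2.0, 0.0)
        got = fw.kernel_projection(p, 1.0, 0)
        assert got == pytest.approx(fw.stick_spherical_mean(2.0), rel=1e-12)
        oracle = quad(lambda t: np.exp(-2.0 * t**2), 0, 1)[0]
        assert got == pytest.approx(oracle, rel=1e-10)

    def test_odd_l_rejected(self):
        p = fw.KernelParams(0.4, 2, 2, 0.6)
        with pytest.raises(ValueError, match="even"):
            fw.kernel_projection(p, 1.0, 3)

    def test_quadrature_convergence(self, rng):
        for _ in range(10):
            p = fw.KernelParams(rng.uniform(0, 1), rng.uniform(0.5, 3),
                                2.5, rng.uniform(0, 2.5))
            b = rng.uniform(0.5, 3)
            for l in (0, 2, 4):
                k64 = fw.kernel_projection(p, b, l, order=64)
                k128 = fw.kernel_projection(p, b, l, order=128)
                assert abs(k64 - k128) < 1e-10

    def test_kl_zero_at_b0_for_higher_l(self):
        p = fw.KernelParams(0.5, 2, 2, 0.7)
        for l in (2, 4):
            assert abs(fw.kernel_projection(p, 0.0, l)) < 1e-14


class TestSynthesis:
    def test_isotropic_voxel_single_exponential(self, proto):
        p = fw.KernelParams(0.0, 1.0, 1.1, 1.1)
        odf = fw.ODFCoefficients(4, np.zeros(14))
        sig = fw.synthesize_signals(p, odf, proto)
        for b, idx in proto.nonzero_shells.items():
            assert np.allclose(sig[idx], np.exp(-b * 1.1), atol=1e-12)
        assert np.allclose(sig[proto.b0_indices], 1.0)

    def test_against_brute_force_convolution(self, proto, rng):
        # direct numerical quadrature of the ODF-kernel convolution
        p = fw.KernelParams(0.55, 2.2, 1.8, 0.6)
        odf = fw.zonal_odf({2: 0.7, 4: 0.55}, axis=(0.3, -0.5, 0.81))
        sig = fw.synthesize_signals(p, odf, proto)
        nodes, weights = sphere_quadrature()
        y = real_sh_basis(nodes, 4)
        odf_vals = 1.0 + y[:, 1:] @ odf.plm
        for v in [5, 30, 50, 80]:
            b = proto.bvals[v]
            k = fw.kernel_signal(p, b, np.abs(nodes @ proto.dirs[v]))
            brute = np.sum(weights * odf_vals * k)
            assert sig[v] == pytest.approx(brute, rel=1e-4)

    def test_rotation_equivariance(self, proto, rng):
        p = fw.KernelParams(0.5, 2.1, 1.9, 0.55)
        rot = random_rotation(rng)
        axis = np.array([0.2, 0.3, np.sqrt(1 - 0.13)])
        sig = fw.synthesize_signals(p, fw.zonal_odf({2: 0.6, 4: 0.45}, axis),
                                    proto)
        proto_rot = Protocol(proto.bvals, proto.dirs @ rot.T)
        sig_rot = fw.synthesize_signals(
            p, fw.zonal_odf({2: 0.6, 4: 0.45}, rot @ axis), proto_rot)
        assert np.allclose(sig, sig_rot, atol=1e-12)


class TestFitSH:
    def test_noise_free_roundtrip(self, proto, rng):
        # synthesize from known coefficients on the 60-direction shell
        idx = proto.nonzero_shells[2.0]
        y = real_sh_basis(proto.dirs[idx], 4)
        coeffs = rng.standard_normal(15)
        signals = np.zeros(proto.n_volumes)
        signals[idx] = y @ coeffs
        signals[proto.b0_indices] = 1.0
        signals[proto.nonzero_shells[1.0]] = 1.0
        fit = fw.fit_sh(signals, proto)
        assert np.allclose(fit.coeffs[2.0][0], coeffs, atol=1e-8)

    def test_twenty_direction_shell_roundtrip(self, proto, rng):
        idx = proto.nonzero_shells[1.0]
        y = real_sh_basis(proto.dirs[idx], 4)
        coeffs = rng.standard_normal(15)
        signals = np.ones(proto.n_volumes)
        signals[idx] = y @ coeffs
        fit = fw.fit_sh(signals, proto)
        assert np.allclose(fit.coeffs[1.0][0], coeffs, atol=1e-6)

    def test_constant_signal_only_l0(self, proto):
        signals = np.full(proto.n_volumes, 0.8)
        fit = fw.fit_sh(signals, proto)
        for b in (1.0, 2.0):
            c = fit.coeffs[b][0]
            assert c[0] == pytest.approx(0.8 * np.sqrt(4 * np.pi), rel=1e-12)
            assert np.allclose(c[1:], 0.0, atol=1e-12)
        assert fit.b0_mean[0] == pytest.approx(0.8)

    def test_degenerate_directions_raise(self):
        bvals = np.concatenate([[0.0], np.ones(20)])
        dirs = np.vstack([np.zeros(3), np.tile([0, 0, 1.0], (20, 1))])
        proto = Protocol(bvals, dirs)
        with pytest.raises(np.linalg.LinAlgError, match="ill-conditioned"):
            fw.fit_sh(np.ones(21), proto)

    def test_lmax_lowered_for_sparse_shell(self, caplog):
        proto = default_protocol(n_b1=8, seed=0)
        with caplog.at_level("WARNING"):
            fit = fw.fit_sh(np.ones(proto.n_volumes), proto)
        assert fit.lmax_per_shell[1.0] == 2
        assert any("lowering lmax" in r.message for r in caplog.records)


class TestRotationalInvariants:
    def test_delta_odf_saturates_all_invariants(self, rng):
        # fully aligned ODF: p_l = 1 for every even l, any orientation
        for _ in range(5):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            inv = fw.zonal_odf({2: 1.0, 4: 1.0}, axis).invariants()
            assert inv[2] == pytest.approx(1.0, abs=1e-9)
            assert inv[4] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_odf_zero(self):
        inv = fw.ODFCoefficients(4, np.zeros(14)).invariants()
        assert inv[2] == 0.0 and inv[4] == 0.0

    def test_master_factorization(self, proto, rng):
        """S_l(b) = p_l |K_l(b)| for arbitrary ODFs, noise-free (<=1e-6)."""
        for _ in range(20):
            p = fw.KernelParams(rng.uniform(0.3, 0.8), rng.uniform(1.5, 2.5),
                                rng.uniform(1.5, 2.5), rng.uniform(0.4, 1.0))
            pl = {2: rng.uniform(0.3, 0.8)}
            pl[4] = pl[2] * rng.uniform(0.75, 0.85)
            odf = fw.random_odf(pl, rng)
            sig = fw.synthesize_signals(p, odf, proto)
            inv = fw.rotational_invariants(fw.fit_sh(sig, proto))
            for j, b in enumerate(inv.bvals):
                for k, l in enumerate((0, 2, 4)):
                    expect = abs(({0: 1.0} | pl)[l]
                                 * fw.kernel_projection(p, b, l))
                    assert inv.values[0, j, k] == pytest.approx(
                        expect, rel=1e-6)

    def test_rotation_invariance(self, proto, rng):
        p = fw.KernelParams(0.5, 2.0, 1.8, 0.6)
        odf = fw.random_odf({2: 0.5, 4: 0.4}, rng)
        base = fw.rotational_invariants(
            fw.fit_sh(fw.synthesize_signals(p, odf, proto), proto)).values
        for _ in range(3):
            rot = random_rotation(rng)
            proto_rot = Protocol(proto.bvals, proto.dirs @ rot.T)
            vals = fw.rotational_invariants(
                fw.fit_sh(fw.synthesize_signals(p, odf, proto_rot),
                          proto_rot)).values
            # rotating the frame jointly leaves the invariants unchanged
            assert np.allclose(vals, base, atol=1e-9)

    def test_s0_monotone_decreasing_in_b(self, rng):
        proto = default_protocol(n_b1=30, n_b2=30, b1=0.5, b2=1.0, seed=0)
        p = fw.KernelParams(0.5, 2.0, 1.8, 0.6)
        sig = fw.synthesize_signals(p, fw.zonal_odf({2: 0.5, 4: 0.4}), proto)
        inv = fw.rotational_invariants(fw.fit_sh(sig, proto))
        s0 = inv.values[0, :, 0]
        assert 1.0 > s0[0] > s0[1] > 0.0


class TestAddNoise:
    def test_infinite_snr_limit(self, rng):
        sig = np.linspace(0.1, 1.0, 50)[None]
        noisy = fw.add_noise(sig, 1e12, rng)
        assert np.allclose(noisy, sig, atol=1e-9)

    def test_gaussian_sigma_monte_carlo(self, rng):
        noisy = fw.add_noise(np.ones((1, 10**6)), 25.0, rng)
        assert np.std(noisy) == pytest.approx(0.04, abs=2e-4)

    def test_rician_high_snr_bias(self, rng):
        # series expansion: E[rician] - s ~ sigma^2 / (2 s)
        snr, s = 20.0, 1.0
        sigma = s / snr
        noisy = fw.add_noise(np.full((1, 10**6), s), snr, rng, model="rician")
        assert np.mean(noisy) - s == pytest.approx(
            sigma**2 / (2 * s), rel=0.15)

    def test_invalid_snr_or_model(self, rng):
        with pytest.raises(ValueError):
            fw.add_noise(np.ones(3), -1.0, rng)
        with pytest.raises(ValueError):
            fw.add_noise(np.ones(3), 10.0, rng, model="poisson")


class TestWatson:
    def test_isotropic_limit(self):
        inv = fw.watson_invariants(0.0)
        assert inv[2] == pytest.approx(0.0, abs=1e-12)
        assert inv[4] == pytest.approx(0.0, abs=1e-12)

    def test_delta_limit(self):
        assert fw.watson_invariants(1e4)[2] > 0.99

    def test_monotone_in_kappa(self):
        kappas = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 20.0, 100.0])
        p2 = np.asarray(fw.watson_invariants(kappas)[2])
        assert np.all(np.diff(p2) > 0)

    def test_kappa_one_against_monte_carlo(self, rng):
        # two independent oracles: adaptive quadrature vs MC average of P2
        p2 = fw.watson_invariants(1.0)[2]
        t = rng.uniform(0, 1, 10**6)
        w = np.exp(1.0 * (t**2 - 1.0))
        mc = np.sum(w * 0.5 * (3 * t**2 - 1)) / np.sum(w)
        assert p2 == pytest.approx(mc, abs=1e-3)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            fw.watson_invariants(-1.0)
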