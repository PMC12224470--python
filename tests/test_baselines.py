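"""Constrained baseline estimators: NODDI, SMT, DKI/WMTI, Watson-WMTI.

Each baseline must be self-consistent on noise-free data generated under
its own constraints, and biased in the documented direction when the
generator violates them.
"""

import numpy as np
import pytest

from smikit._sph import random_unit_vectors
from smikit.estimators import NODDI, SMT, WMTI, WatsonWMTI, dki_fit
from smikit.estimators.dki import (apparent_kurtosis, dki_design_matrix,
                                   fa_from_tensors)
from smikit.estimators.smt import smt_spherical_mean
from smikit.forward import (KernelParams, stick_spherical_mean,
                            synthesize_zonal, watson_invariants)
from smikit.protocol import default_protocol


class TestNODDI:
    def test_self_consistency_noise_free(self, proto, rng):
        # generator obeys NODDI's constraints: fixed diffusivities,
        # tortuosity, Watson (p2, p4) pair
        kappa = 3.0
        inv = watson_invariants(kappa)
        f = 0.6
        sig = synthesize_zonal(
            KernelParams(f, 1.7, 1.7, 1.7 * (1 - f)),
            {2: inv[2], 4: inv[4]}, random_unit_vectors(3, rng), proto)
        est = NODDI(protocol=proto).fit().predict(sig)
        assert np.allclose(est["f"], f, atol=1e-3)
        assert np.allclose(est["p2"], inv[2], atol=1e-3)
        assert not est["flagged"].any()

    def test_isotropic_generator_gives_zero_p2(self, proto):
        f = 0.4
        sig = synthesize_zonal(KernelParams(f, 1.7, 1.7, 1.7 * (1 - f)),
                               {2: 0.0, 4: 0.0},
                               np.array([[0.0, 0.0, 1.0]]), proto)
        est = NODDI(protocol=proto).fit().predict(sig)
        assert est["p2"].iloc[0] == pytest.approx(0.0, abs=1e-3)

    def test_da_misspecification_biases_f_downward(self, proto, rng):
        # true Da above the fixed 1.7 lowers the estimated f, the same sign
        # as the negative Da -> f_hat sensitivity of this estimator
        inv = watson_invariants(3.0)
        axes = random_unit_vectors(20, rng)
        noddi = NODDI(protocol=proto).fit()
        f_true = 0.55
        ests = {}
        for da in (1.7, 2.5):
            sig = synthesize_zonal(
                KernelParams(f_true, da, 1.7, 1.7 * (1 - f_true)),
                {2: inv[2], 4: inv[4]}, axes, proto)
            ests[da] = noddi.predict(sig)["f"].mean()
        assert ests[2.5] < ests[1.7] - 0.02


class TestSMT:
    def test_self_consistency_noise_free(self, proto, rng):
        f, d = 0.5, 2.0
        sig = synthesize_zonal(KernelParams(f, d, d, d * (1 - f)),
                               {2: 0.6, 4: 0.45},
                               random_unit_vectors(3, rng), proto)
        est = SMT(protocol=proto).fit().predict(sig)
        assert np.allclose(est["f"], f, atol=1e-6)
        assert np.allclose(est["da"], d, atol=1e-6)

    def test_series_branch_matches_closed_form(self):
        # h(x) = sqrt(pi/4x) erf(sqrt(x)): series below 1e-6 vs erf above
        from scipy.special import erf

        for x in (1e-6, 9.9e-7, 5e-7):
            closed = np.sqrt(np.pi / (4 * x)) * erf(np.sqrt(x))
            assert stick_spherical_mean(x) == pytest.approx(closed, abs=1e-9)

    def test_zero_f_recovers_pure_diffusivity(self, proto):
        d = 1.4
        sig = synthesize_zonal(KernelParams(0.0, d, d, d), {2: 0.0, 4: 0.0},
                               np.array([[0.0, 0.0, 1.0]]), proto)
        est = SMT(protocol=proto).fit().predict(sig)
        assert est["da"].iloc[0] == pytest.approx(d, abs=1e-4)
        assert est["f"].iloc[0] == pytest.approx(0.0, abs=1e-4)
        assert est["flagged"].iloc[0]  # f pinned at the bound is flagged

    def test_spherical_mean_model_matches_kernel_projection(self):
        from smikit.forward import kernel_projection

        f, d = 0.45, 2.1
        p = KernelParams(f, d, d, d * (1 - f))
        for b in (1.0, 2.0):
            assert smt_spherical_mean(b, f, d) == pytest.approx(
                kernel_projection(p, b, 0), rel=1e-10)


class TestDKI:
    def test_pure_gaussian_tensor_zero_kurtosis(self, proto):
        d = np.diag([2.0, 0.7, 0.7])
        bg = np.einsum("vi,ij,vj->v", proto.dirs, d, proto.dirs)
        sig = np.exp(-proto.bvals * bg)[None]
        fit = dki_fit(sig, proto)
        assert np.allclose(fit.d[0], d, atol=1e-8)
        assert np.max(np.abs(fit.w[0])) < 1e-6

    def test_isotropic_mixture_mean_kurtosis(self):
        # f=1/2 mixture of D=1 and D=2 isotropic: MK = 3 Var/Mean^2 = 1/3
        proto = default_protocol(b1=0.25, b2=0.5, seed=0)
        sig = (0.5 * np.exp(-proto.bvals * 1.0)
               + 0.5 * np.exp(-proto.bvals * 2.0))[None]
        fit = dki_fit(sig, proto)
        mk = apparent_kurtosis(fit, random_unit_vectors(
            64, np.random.default_rng(0))).mean()
        assert mk == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_fa_closed_form(self):
        # FA = sqrt(3/2 sum (l_i - l_mean)^2 / sum l_i^2)
        d = np.diag([2.0, 0.7, 0.7])
        ev = np.array([2.0, 0.7, 0.7])
        oracle = np.sqrt(1.5 * np.sum((ev - ev.mean()) ** 2)
                         / np.sum(ev**2))
        assert fa_from_tensors(d) == pytest.approx(oracle, abs=1e-12)
        assert fa_from_tensors(d) == pytest.approx(0.5825, abs=5e-4)

    def test_design_matrix_shape(self, proto):
        assert dki_design_matrix(proto).shape == (84, 22)


@pytest.fixture(scope="module")
def small_b_proto():
    """Moderate-b protocol: keeps the DKI cumulant-truncation bias small,
    isolating the moment-inversion logic under test."""
    return default_protocol(n_b1=30, n_b2=60, b1=0.4, b2=0.8, seed=2)


def delta_odf_signals(params, axis, protocol):
    """True perfectly-aligned voxel: the kernel itself along ``axis``."""
    from smikit.forward import kernel_signal

    xi = np.abs(protocol.dirs @ np.asarray(axis, dtype=float))
    return np.array([kernel_signal(params, b, x)
                     for b, x in zip(protocol.bvals, xi)])[None]


class TestWMTI:
    def test_aligned_fibers_self_consistency(self, small_b_proto):
        # delta ODF (perfect alignment) is WMTI's validity regime
        truth = dict(f=0.5, da=2.0, depar=2.4, deperp=0.8)
        sig = delta_odf_signals(KernelParams(**truth), [0.0, 0.0, 1.0],
                                small_b_proto)
        est = WMTI(protocol=small_b_proto).fit().predict(sig)
        assert est["f"].iloc[0] == pytest.approx(truth["f"], abs=0.05)
        assert est["da"].iloc[0] <= est["depar"].iloc[0] + 1e-9  # branch

    def test_vanishing_f_gives_zero_kurtosis_and_f(self, proto):
        # f = 0: a single Gaussian compartment, so K(n) = 0 along every n
        d = np.diag([0.8, 0.8, 2.0])
        bg = np.einsum("vi,ij,vj->v", proto.dirs, d, proto.dirs)
        sig = np.exp(-proto.bvals * bg)[None]
        fit = dki_fit(sig, proto)
        kn = apparent_kurtosis(fit, random_unit_vectors(
            100, np.random.default_rng(1)))
        assert np.max(np.abs(kn)) < 1e-8
        est = WMTI(protocol=proto).fit().predict(sig)
        assert est["f"].iloc[0] < 1e-4

    def test_dispersion_biases_da_downward(self, proto, rng):
        # WMTI assumes aligned fibers; dispersion (lower p2) leaks into Da
        # with the positive p2 -> Da_hat sensitivity documented for it
        wmti = WMTI(protocol=proto).fit()
        truth = dict(f=0.5, da=2.2, depar=2.2, deperp=0.7)
        axes = random_unit_vectors(10, rng)
        da_aligned = wmti.predict(synthesize_zonal(
            KernelParams(**truth), {2: 0.95, 4: 0.9}, axes, proto))
        da_disp = wmti.predict(synthesize_zonal(
            KernelParams(**truth), {2: 0.5, 4: 0.4}, axes, proto))
        assert da_disp["da"].mean() < da_aligned["da"].mean() - 0.05


class TestWatsonWMTI:
    def test_watson_generator_recovery(self, small_b_proto, rng):
        truth = dict(f=0.5, da=2.4, depar=1.8, deperp=0.6)
        inv = watson_invariants(8.0, lmax=8)
        sig = synthesize_zonal(
            KernelParams(**truth), {l: inv[l] for l in (2, 4, 6, 8)},
            random_unit_vectors(3, rng), small_b_proto, lmax=8)
        est = WatsonWMTI(protocol=small_b_proto).fit().predict(sig)
        assert np.allclose(est["f"], truth["f"], atol=0.1)
        assert np.allclose(est["da"], truth["da"], atol=0.15)
        assert np.allclose(est["p2"], inv[2], atol=0.1)

    def test_branch_da_geq_depar(self, small_b_proto, rng):
        inv = watson_invariants(4.0, lmax=8)
        sig = synthesize_zonal(
            KernelParams(0.4, 2.2, 1.9, 0.7),
            {l: inv[l] for l in (2, 4, 6, 8)},
            random_unit_vectors(5, rng), small_b_proto, lmax=8)
        est = WatsonWMTI(protocol=small_b_proto).fit().predict(sig)
        assert (est["da"] >= est["depar"] - 1e-9).all()

    def test_aligned_limit_agrees_with_wmti(self, small_b_proto):
        # near-delta Watson: both variants see nearly aligned fibers
        inv = watson_invariants(1e4, lmax=8)
        sig = synthesize_zonal(
            KernelParams(0.5, 2.2, 2.0, 0.6),
            {l: inv[l] for l in (2, 4, 6, 8)},
            np.array([[0.0, 0.0, 1.0]]), small_b_proto, lmax=8)
        w = WMTI(protocol=small_b_proto).fit().predict(sig)
        ww = WatsonWMTI(protocol=small_b_proto).fit().predict(sig)
        assert ww["f"].iloc[0] == pytest.approx(w["f"].iloc[0], abs=0.1)
        assert ww["deperp"].iloc[0] == pytest.approx(
            w["deperp"].iloc[0], abs=0.1)
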