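"""Standard Model forward signal: kernel, ODF convolution, invariants, noise.

A white-matter voxel is a collection of identical fiber fascicles oriented
according to an ODF P(n).  Each fascicle contributes a two-compartment
kernel K(b, xi), xi = g.n: an intra-axonal "stick" (diffusivity Da along the
axis, zero across) of water fraction f, and an extra-axonal axially
symmetric Gaussian compartment (De_par, De_perp).  An optional isotropic
free-water term (fraction fiso, diffusivity D0 = 3 um^2/ms) can be added.

The signal along gradient g is the spherical convolution of the kernel with
the ODF.  In the (real, even-degree) spherical-harmonic basis this
factorizes as S_lm(b) = p_lm * K_l(b), where K_l is the Legendre projection
of the kernel, giving the per-shell rotational invariants

    S_l(b) = p_l * K_l(b),       l = 0, 2, 4, ...

with p_0 = 1 and 0 <= p_l <= 1 (p_l = 1 for a fully aligned ODF).  These
invariants are the data features used by all estimators in this package.

Units: diffusivities in um^2/ms, b-values in ms/um^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from ._sph import even_degrees, legendre, n_even_coeffs, real_sh_basis
from .protocol import Protocol

__all__ = [
    "D0_FREE_WATER",
    "KernelParams",
    "ODFCoefficients",
    "SignalInvariants",
    "ShellCoefficients",
    "kernel_signal",
    "kernel_projection",
    "kernel_projections",
    "zonal_odf",
    "random_odf",
    "synthesize_signals",
    "synthesize_zonal",
    "fit_sh",
    "rotational_invariants",
    "add_noise",
    "watson_invariants",
    "watson_cos_moments",
    "stick_spherical_mean",
]

log = logging.getLogger(__name__)

D0_FREE_WATER = 3.0  # um^2/ms, free-water diffusivity ceiling

_GL_ORDER = 64  # Gauss-Legendre order for Legendre projections on [0, 1]
_gl_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre_01(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order not in _gl_cache:
        t, w = np.polynomial.legendre.leggauss(order)
        _gl_cache[order] = ((t + 1.0) / 2.0, w / 2.0)
    return _gl_cache[order]


# ---------------------------------------------------------------------------
# parameters


@dataclass
class KernelParams:
    """Fascicle kernel parameters; fields may be scalars or aligned arrays.

    f        intra-axonal (stick) water fraction, in [0, 1]
    da       intra-axonal axial diffusivity (um^2/ms)
    depar    extra-axonal axial diffusivity (um^2/ms)
    deperp   extra-axonal radial diffusivity (um^2/ms), <= depar
    s0       proton-density signal scale at b=0
    fiso     optional free-water (CSF) fraction, f + fiso <= 1
    """

    f: float | np.ndarray
    da: float | np.ndarray
    depar: float | np.ndarray
    deperp: float | np.ndarray
    s0: float | np.ndarray = 1.0
    fiso: float | np.ndarray = 0.0
    d0: float = D0_FREE_WATER

    def __post_init__(self):
        f, da, dpar, dperp, fiso = (np.asarray(x, dtype=float) for x in
                                    (self.f, self.da, self.depar,
                                     self.deperp, self.fiso))
        eps = 1e-12
        if np.any(f < -eps) or np.any(f > 1 + eps):
            raise ValueError("f must lie in [0, 1]")
        if np.any(fiso < -eps) or np.any(f + fiso > 1 + eps):
            raise ValueError("fiso must be >= 0 with f + fiso <= 1")
        for name, d in (("da", da), ("depar", dpar), ("deperp", dperp)):
            if np.any(d < -eps) or np.any(d > self.d0 + eps):
                raise ValueError(f"{name} must lie in [0, {self.d0}] um^2/ms")
        if np.any(dperp > dpar + 1e-9):
            raise ValueError("deperp must not exceed depar")

    def broadcast(self) -> tuple[np.ndarray, ...]:
        return np.broadcast_arrays(
            *(np.asarray(x, dtype=float) for x in
              (self.f, self.da, self.depar, self.deperp, self.s0, self.fiso)))


# ---------------------------------------------------------------------------
# kernel


def kernel_signal(params: KernelParams, b, xi):
    """Fascicle signal K(b, xi) for gradient/axis cosine xi in [0, 1]."""
    b = np.asarray(b, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if np.any(xi < -1e-12) or np.any(xi > 1 + 1e-12):
        raise ValueError("xi must lie in [0, 1]")
    f, da, dpar, dperp, s0, fiso = params.broadcast()
    xi2 = xi**2
    intra = np.exp(-b * da * xi2)
    extra = np.exp(-b * dpar * xi2 - b * dperp * (1.0 - xi2))
    free = np.exp(-b * params.d0)
    return s0 * (f * intra + (1.0 - f - fiso) * extra + fiso * free)


def kernel_projection(params: KernelParams, b: float, l: int,
                      order: int = _GL_ORDER):
    """Legendre projection K_l(b) = int_0^1 K(b, xi) P_l(xi) dxi.

    Fixed-order Gauss-Legendre quadrature; the integrand is smooth so the
    default order 64 is converged to machine precision for physical b.
    """
    if l % 2 or l < 0:
        raise ValueError(f"l must be even and non-negative, got {l}")
    x, w = _gauss_legendre_01(order)
    bc = params.broadcast()
    scalar = bc[0].ndim == 0
    f, da, dpar, dperp, s0, fiso = (np.atleast_1d(v)[..., None] for v in bc)
    x2 = x**2
    anis = f * np.exp(-b * da * x2) + (1.0 - f - fiso) * np.exp(
        -b * dpar * x2 - b * dperp * (1.0 - x2))
    kl = s0[..., 0] * (anis @ (w * legendre(l, x)))
    if l == 0:
        kl = kl + s0[..., 0] * fiso[..., 0] * np.exp(-b * params.d0)
    return float(kl[0]) if scalar else kl


def kernel_projections(params: KernelParams, bvals, lmax: int = 4,
                       order: int = _GL_ORDER) -> np.ndarray:
    """Stacked K_l(b): shape params_shape + (n_b, n_l) for even l <= lmax."""
    bvals = np.atleast_1d(np.asarray(bvals, dtype=float))
    ls = even_degrees(lmax)
    out = [np.stack([np.asarray(kernel_projection(params, b, l, order))
                     for l in ls], axis=-1) for b in bvals]
    return np.stack(out, axis=-2)


def stick_spherical_mean(bd) -> np.ndarray:
    """Orientation average of exp(-b*D*xi^2): sqrt(pi/(4bD)) erf(sqrt(bD)).

    Series branch below bd = 1e-6 for numerical stability at bd -> 0.
    """
    from scipy.special import erf

    bd = np.asarray(bd, dtype=float)
    out = np.empty_like(bd)
    small = bd < 1e-6
    bds = np.where(small, 1.0, bd)
    out = np.sqrt(np.pi / (4.0 * bds)) * erf(np.sqrt(bds))
    series = 1.0 - bd / 3.0 + bd**2 / 10.0 - bd**3 / 42.0
    return np.where(small, series, out)


# ---------------------------------------------------------------------------
# ODFs


@dataclass
class ODFCoefficients:
    """Real even-degree SH coefficients of an ODF, excluding l=0.

    The l=0 coefficient is fixed by the unit-mass normalization of the ODF
    (p_00 = sqrt(4 pi) in this basis, i.e. p_0 = 1).  ``plm`` is ordered
    (2,-2)...(2,2), (4,-4)...(4,4), ... up to ``lmax``.
    """

    lmax: int
    plm: np.ndarray

    def __post_init__(self):
        self.plm = np.asarray(self.plm, dtype=float).ravel()
        expected = n_even_coeffs(self.lmax) - 1
        if len(self.plm) != expected:
            raise ValueError(
                f"expected {expected} coefficients for lmax={self.lmax}, "
                f"got {len(self.plm)}")

    def blocks(self) -> dict[int, np.ndarray]:
        out, i = {}, 0
        for l in even_degrees(self.lmax)[1:]:
            out[l] = self.plm[i:i + 2 * l + 1]
            i += 2 * l + 1
        return out

    def invariants(self) -> dict[int, float]:
        """Rotational invariants p_l = sqrt(sum_m p_lm^2 / (4 pi (2l+1)))."""
        inv = {0: 1.0}
        for l, c in self.blocks().items():
            inv[l] = float(np.sqrt(np.sum(c**2) / (4.0 * np.pi * (2 * l + 1))))
        return inv


def zonal_odf(pl: dict[int, float], axis=(0.0, 0.0, 1.0),
              lmax: int | None = None) -> ODFCoefficients:
    """Axially symmetric ODF with prescribed invariants p_l about ``axis``.

    Rotating a zonal harmonic gives p_lm = 4 pi p_l Y_lm(axis), which
    reproduces the requested invariants exactly for any axis.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    lmax = lmax if lmax is not None else max(pl)
    y = real_sh_basis(axis, lmax)[0]
    coeffs, i = [], 1
    for l in even_degrees(lmax)[1:]:
        coeffs.append(4.0 * np.pi * pl.get(l, 0.0) * y[i:i + 2 * l + 1])
        i += 2 * l + 1
    return ODFCoefficients(lmax, np.concatenate(coeffs))


def random_odf(pl: dict[int, float], rng: np.random.Generator,
               lmax: int | None = None) -> ODFCoefficients:
    """Random (generally non-zonal) ODF with prescribed invariants p_l."""
    lmax = lmax if lmax is not None else max(pl)
    coeffs = []
    for l in even_degrees(lmax)[1:]:
        v = rng.standard_normal(2 * l + 1)
        norm = np.linalg.norm(v)
        target = pl.get(l, 0.0) * np.sqrt(4.0 * np.pi * (2 * l + 1))
        coeffs.append(v * (target / norm))
    return ODFCoefficients(lmax, np.concatenate(coeffs))


# ---------------------------------------------------------------------------
# synthesis


def synthesize_signals(params: KernelParams, odf: ODFCoefficients,
                       protocol: Protocol) -> np.ndarray:
    """Noise-free per-volume signals for one voxel via S_lm = p_lm K_l."""
    signals = np.empty(protocol.n_volumes)
    b0 = protocol.b0_indices
    s0 = float(np.asarray(params.s0))
    signals[b0] = s0
    blocks = odf.blocks()
    for b, idx in protocol.nonzero_shells.items():
        kl = {l: float(kernel_projection(params, b, l))
              for l in even_degrees(odf.lmax)}
        y = real_sh_basis(protocol.dirs[idx], odf.lmax)
        s = np.full(len(idx), kl[0])  # l=0 term: p_00 K_0 Y_00 = K_0
        i = 1
        for l in even_degrees(odf.lmax)[1:]:
            s += y[:, i:i + 2 * l + 1] @ (blocks[l] * kl[l])
            i += 2 * l + 1
        signals[idx] = s
    return signals


def synthesize_zonal(params: KernelParams, pl: dict[int, np.ndarray],
                     axes: np.ndarray, protocol: Protocol,
                     lmax: int = 4) -> np.ndarray:
    """Vectorized noise-free signals for n voxels with zonal ODFs.

    ``pl`` maps even l >= 2 to per-voxel invariants; ``axes`` is (n, 3).
    Uses the addition theorem: S(b, g) = sum_l (2l+1) K_l(b) p_l P_l(g.u).
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    n = axes.shape[0]
    ls = even_degrees(lmax)
    signals = np.empty((n, protocol.n_volumes))
    s0 = np.broadcast_to(np.asarray(params.s0, dtype=float), (n,))
    signals[:, protocol.b0_indices] = s0[:, None]
    for b, idx in protocol.nonzero_shells.items():
        cosines = axes @ protocol.dirs[idx].T  # (n, n_dirs)
        kl = {l: np.broadcast_to(
            np.asarray(kernel_projection(params, b, l)), (n,))
            for l in ls}
        s = np.repeat(kl[0][:, None], len(idx), axis=1)
        for l in ls[1:]:
            p = np.broadcast_to(np.asarray(pl.get(l, 0.0), dtype=float), (n,))
            s = s + (2 * l + 1) * (kl[l] * p)[:, None] * legendre(l, cosines)
        signals[:, idx] = s
    return signals


# ---------------------------------------------------------------------------
# SH fitting and rotational invariants


@dataclass
class ShellCoefficients:
    """Per-shell real SH coefficients of measured signals.

    coeffs maps nonzero-shell b -> (n_vox, n_coeffs) arrays; per-shell lmax
    may be lower than requested when a shell has too few directions.
    """

    coeffs: dict[float, np.ndarray]
    lmax_per_shell: dict[float, int]
    b0_mean: np.ndarray


def fit_sh(signals: np.ndarray, protocol: Protocol, lmax: int = 4,
           cond_max: float = 1e8) -> ShellCoefficients:
    """Per-shell linear least-squares fit of real even-degree harmonics.

    The b=0 shell is reduced to its mean.  If a shell has fewer directions
    than SH coefficients, its lmax is lowered with a logged warning.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != protocol.n_volumes:
        raise ValueError(
            f"signals have {signals.shape[1]} volumes, protocol expects "
            f"{protocol.n_volumes}")
    b0_mean = signals[:, protocol.b0_indices].mean(axis=1)
    coeffs, lmaxes = {}, {}
    for b, idx in protocol.nonzero_shells.items():
        shell_lmax = lmax
        while n_even_coeffs(shell_lmax) > len(idx) and shell_lmax > 0:
            shell_lmax -= 2
        if shell_lmax < lmax:
            log.warning("shell b=%g has %d directions; lowering lmax to %d",
                        b, len(idx), shell_lmax)
        y = real_sh_basis(protocol.dirs[idx], shell_lmax)
        cond = np.linalg.cond(y)
        if cond > cond_max:
            raise np.linalg.LinAlgError(
                f"SH design for shell b={b} is ill-conditioned "
                f"(cond={cond:.2e}); directions are degenerate")
        coeffs[b] = signals[:, idx] @ np.linalg.pinv(y).T
        lmaxes[b] = shell_lmax
    return ShellCoefficients(coeffs, lmaxes, b0_mean)


@dataclass
class SignalInvariants:
    """Per-shell rotational invariants S_l(b), l in {0, 2, 4}.

    values has shape (n_vox, n_shells, n_l); shells sorted by b.  When
    ``normalized`` is True the values have been divided by the measured
    b=0 mean, making the proton density s0 a nuisance parameter.
    """

    bvals: np.ndarray
    ls: tuple[int, ...]
    values: np.ndarray
    b0_mean: np.ndarray
    normalized: bool = False

    def features(self) -> np.ndarray:
        """Flat (n_vox, n_shells * n_l) feature matrix, b0-normalized."""
        vals = self.values
        if not self.normalized:
            vals = vals / self.b0_mean[:, None, None]
        return vals.reshape(vals.shape[0], -1)


def rotational_invariants(fit: ShellCoefficients, lmax: int = 4,
                          normalize: bool = False) -> SignalInvariants:
    """Rotational invariants S_l(b) = sqrt(sum_m S_lm^2 / (4 pi (2l+1)))."""
    bvals = np.array(sorted(fit.coeffs))
    ls = tuple(even_degrees(lmax))
    n_vox = len(fit.b0_mean)
    values = np.zeros((n_vox, len(bvals), len(ls)))
    for j, b in enumerate(bvals):
        c = fit.coeffs[b]
        i = 0
        for k, l in enumerate(even_degrees(fit.lmax_per_shell[b])):
            if l > lmax:
                break
            block = c[:, i:i + 2 * l + 1]
            values[:, j, k] = np.sqrt(
                np.sum(block**2, axis=1) / (4.0 * np.pi * (2 * l + 1)))
            i += 2 * l + 1
    b0_mean = fit.b0_mean
    if normalize:
        safe = np.where(np.abs(b0_mean) > 1e-12, b0_mean, 1.0)
        values = values / safe[:, None, None]
    return SignalInvariants(bvals, ls, values, b0_mean, normalized=normalize)


# ---------------------------------------------------------------------------
# noise


def add_noise(signals: np.ndarray, snr: float, rng: np.random.Generator,
              model: str = "gaussian", s0=1.0) -> np.ndarray:
    """Add noise at the given SNR (referenced to the b=0 signal s0).

    gaussian: s + N(0, sigma^2);  rician: sqrt((s+e1)^2 + e2^2) with
    e1, e2 ~ N(0, sigma^2); sigma = s0 / snr.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    signals = np.asarray(signals, dtype=float)
    sigma = np.asarray(s0, dtype=float) / snr
    if np.ndim(sigma) == 1:
        sigma = sigma[:, None]
    if model == "gaussian":
        return signals + sigma * rng.standard_normal(signals.shape)
    if model == "rician":
        e1 = sigma * rng.standard_normal(signals.shape)
        e2 = sigma * rng.standard_normal(signals.shape)
        return np.sqrt((signals + e1) ** 2 + e2**2)
    raise ValueError(f"unknown noise model {model!r}")


# ---------------------------------------------------------------------------
# Watson ODFs


def watson_invariants(kappa, lmax: int = 4) -> dict[int, np.ndarray]:
    """Rotational invariants p_l of a Watson ODF with concentration kappa.

    The Watson density on the sphere is W(n) ~ exp(kappa (u.n)^2); its
    invariants are p_l = <P_l(u.n)> under the density, computed by adaptive
    quadrature.  Monotone increasing in kappa; p_l -> 1 as kappa -> inf.
    """
    scalar = np.ndim(kappa) == 0
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    ls = even_degrees(lmax)[1:]
    out = {l: np.empty(len(kappa)) for l in ls}
    for i, k in enumerate(kappa):
        # factor exp(-k) out of exp(k t^2) to avoid overflow at large kappa
        z = quad(lambda t: np.exp(k * (t**2 - 1.0)), 0.0, 1.0)[0]
        for l in ls:
            num = quad(lambda t: np.exp(k * (t**2 - 1.0)) * legendre(l, t),
                       0.0, 1.0)[0]
            out[l][i] = num / z
    return {l: (float(v[0]) if scalar else v) for l, v in out.items()}


def watson_cos_moments(kappa) -> tuple[np.ndarray, np.ndarray]:
    """Watson moments c2 = <cos^2 psi>, c4 = <cos^4 psi> of the fiber axis.

    Derived from the invariants: c2 = (2 p2 + 1)/3,
    c4 = (8 p4 + 30 c2 - 3)/35.
    """
    inv = watson_invariants(kappa, lmax=4)
    c2 = (2.0 * np.asarray(inv[2]) + 1.0) / 3.0
    c4 = (8.0 * np.asarray(inv[4]) + 30.0 * c2 - 3.0) / 35.0
    return c2, c4
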