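"""Real spherical-harmonic basis and direction-set utilities.

The basis is real, orthonormal with respect to the solid-angle measure
dOmega = sin(theta) dtheta dphi (integral of Y_lm * Y_l'm' over the sphere
equals the Kronecker delta), and free of the Condon-Shortley phase.  Under
the addition theorem, sum_m Y_lm(u)^2 = (2l+1)/(4*pi) for any unit vector u.
Only even degrees are used throughout the package (antipodal symmetry of
diffusion signals).
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "even_degrees",
    "n_even_coeffs",
    "real_sh_basis",
    "legendre",
    "fibonacci_hemisphere",
    "random_rotation",
    "random_unit_vectors",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def even_degrees(lmax: int) -> list[int]:
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be even and non-negative, got {lmax}")
    return list(range(0, lmax + 1, 2))


def n_even_coeffs(lmax: int) -> int:
    """Number of (l, m) pairs with even l <= lmax (e.g. 15 for lmax=4)."""
    return sum(2 * l + 1 for l in even_degrees(lmax))


def _cart_to_sph(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    return theta, phi


def real_sh_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Design matrix of real even-l spherical harmonics at unit vectors.

    Returns an array of shape (n_dirs, n_even_coeffs(lmax)); columns are
    ordered (l, m) = (0,0), (2,-2)...(2,2), (4,-4)...(4,4), ...
    """
    theta, phi = _cart_to_sph(dirs)
    cols = []
    for l in even_degrees(lmax):
        # scipy returns all orders m = -l..l at once
        ylm = sph_harm_y(l, np.arange(-l, l + 1), theta[:, None], phi[:, None])
        for m in range(-l, l + 1):
            y = ylm[:, m + l]
            cs = (-1.0) ** m  # cancel the Condon-Shortley phase
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * cs * y.real)
            else:
                cols.append(np.sqrt(2.0) * cs * sph_harm_y(
                    l, -m, theta, phi).imag)
    return np.stack(cols, axis=-1)


def legendre(l: int, x: np.ndarray) -> np.ndarray:
    return eval_legendre(l, x)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (z > 0).

    Spherical-Fibonacci layout; adequate for axially symmetric (g ~ -g)
    diffusion sampling.
    """
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = 2.0 * np.pi * i / _GOLDEN**2
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
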