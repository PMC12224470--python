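"""Diffusion kurtosis imaging: weighted linear least-squares tensor fit.

The log-signal is modeled as a cumulant expansion in the b-value,

    ln S(b, g) = ln s0 - b g_i g_j D_ij + (b^2 / 6) MD^2 g_i g_j g_k g_l W_ijkl

with D the 3x3 diffusion tensor, W the fully symmetric fourth-order
kurtosis tensor and MD = tr(D)/3.  The fit is linear in (ln s0, D, V) with
V = MD^2 W, solved per voxel by weighted least squares (weights = squared
signal, the standard heteroscedasticity correction for log-linearized
fits); W is recovered as V / MD^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..protocol import Protocol

__all__ = ["DKIFit", "dki_fit", "dki_design_matrix", "fa_from_tensors",
           "apparent_diffusion", "apparent_kurtosis"]

log = logging.getLogger(__name__)

# unique index sets of symmetric tensors with multinomial multiplicities
_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1, 1, 1, 2, 2, 2], dtype=float)
_W_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2),
    (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
_W_MULT = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12],
                   dtype=float)


@dataclass
class DKIFit:
    """Fitted diffusion (D) and kurtosis (W) tensors per voxel."""

    s0: np.ndarray        # (n,)
    d: np.ndarray         # (n, 3, 3)
    w: np.ndarray         # (n, 3, 3, 3, 3), fully symmetric
    md: np.ndarray        # (n,) mean diffusivity

    def __len__(self) -> int:
        return len(self.s0)


def dki_design_matrix(protocol: Protocol) -> np.ndarray:
    """(n_volumes, 22) design: [1, -b gg (6), b^2/6 gggg (15)]."""
    g = protocol.dirs
    b = protocol.bvals
    cols = [np.ones(len(b))]
    for (i, j), m in zip(_D_IDX, _D_MULT):
        cols.append(-b * m * g[:, i] * g[:, j])
    for (i, j, k, l), m in zip(_W_IDX, _W_MULT):
        cols.append(b**2 / 6.0 * m * g[:, i] * g[:, j] * g[:, k] * g[:, l])
    return np.stack(cols, axis=1)


def _unpack_sym2(v: np.ndarray) -> np.ndarray:
    out = np.zeros(v.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(_D_IDX):
        out[..., i, j] = v[..., c]
        out[..., j, i] = v[..., c]
    return out


def _unpack_sym4(v: np.ndarray) -> np.ndarray:
    from itertools import permutations

    out = np.zeros(v.shape[:-1] + (3, 3, 3, 3))
    for c, idx in enumerate(_W_IDX):
        for perm in set(permutations(idx)):
            out[(..., *perm)] = v[..., c]
    return out


def dki_fit(signals: np.ndarray, protocol: Protocol,
            eps: float = 1e-10) -> DKIFit:
    """Weighted linear least-squares DKI fit of per-voxel signals.

    Requires two nonzero shells plus b=0 (>= 22 usable volumes).
    Non-positive signals are clipped at ``eps`` with a logged warning.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if protocol.n_volumes < 22:
        raise ValueError("DKI needs >= 22 volumes (22 free parameters)")
    if len(protocol.nonzero_shells) < 2:
        raise ValueError("DKI needs >= 2 nonzero shells")
    n_clip = int(np.sum(signals <= 0))
    if n_clip:
        log.warning("clipping %d non-positive signals at %g before the "
                    "log-transform", n_clip, eps)
    s = np.clip(signals, eps, None)
    x = dki_design_matrix(protocol)
    y = np.log(s)
    wgt = s**2
    xtwx = np.einsum("vi,nv,vj->nij", x, wgt, x)
    xtwy = np.einsum("vi,nv,nv->ni", x, wgt, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    s0 = np.exp(beta[:, 0])
    d = _unpack_sym2(beta[:, 1:7])
    v = _unpack_sym4(beta[:, 7:22])
    md = np.trace(d, axis1=1, axis2=2) / 3.0
    safe_md2 = np.where(np.abs(md) > 1e-12, md**2, 1.0)
    w = v / safe_md2[:, None, None, None, None]
    return DKIFit(s0=s0, d=d, w=w, md=md)


def apparent_diffusion(fit: DKIFit, dirs: np.ndarray) -> np.ndarray:
    """D(n) = n_i n_j D_ij, shape (n_vox, n_dirs)."""
    dirs = np.atleast_2d(dirs)
    return np.einsum("nij,mi,mj->nm", fit.d, dirs, dirs)


def apparent_kurtosis(fit: DKIFit, dirs: np.ndarray,
                      floor: float = 1e-12) -> np.ndarray:
    """K(n) = MD^2 W(n) / D(n)^2, shape (n_vox, n_dirs)."""
    dirs = np.atleast_2d(dirs)
    wn = np.einsum("nijkl,mi,mj,mk,ml->nm", fit.w, dirs, dirs, dirs, dirs)
    dn = apparent_diffusion(fit, dirs)
    dn2 = np.where(np.abs(dn) > floor, dn**2, floor)
    return fit.md[:, None] ** 2 * wn / dn2


def fa_from_tensors(d: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of 3x3 tensors (stacked on leading axes).

    Non-finite tensors yield FA = NaN.
    """
    d = np.asarray(d, dtype=float)
    single = d.ndim == 2
    d = d.reshape(-1, 3, 3)
    fa = np.full(d.shape[0], np.nan)
    finite = np.all(np.isfinite(d), axis=(1, 2))
    if np.any(finite):
        ev = np.linalg.eigvalsh(d[finite])
        mean = ev.mean(axis=1, keepdims=True)
        num = np.sum((ev - mean) ** 2, axis=1)
        den = np.sum(ev**2, axis=1)
        val = np.sqrt(1.5 * num / np.where(den > 0, den, 1.0))
        val[den <= 0] = 0.0
        fa[finite] = val
    return float(fa[0]) if single else fa
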