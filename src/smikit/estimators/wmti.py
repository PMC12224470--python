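"""WMTI-style estimators: Standard Model parameters from DKI tensors.

WMTI assumes well-aligned fibers, decomposing the apparent diffusion and
kurtosis along each direction n into a two-compartment mixture:

    D(n) = f Da(n) + (1 - f) De(n)
    K(n) = 3 f (1 - f) (De(n) - Da(n))^2 / D(n)^2

The axonal water fraction follows from the direction of maximal kurtosis,
f = max_n K(n) / (K(n) + 3), and the per-direction compartment
diffusivities from the square-root branches of the mixture relations; the
branch with Da <= De_par (minus branch for the intra-axonal compartment)
defines classic WMTI.  The intra-axonal tensor's trace gives Da; the
extra-axonal tensor's axial/radial eigenvalues give De_par, De_perp.

W-WMTI (Watson-WMTI, experimental here) instead assumes a Watson ODF and
the opposite branch Da >= De_par; it matches the model-implied directional
moments D(theta), K(theta) at theta = 0, 45, 90 degrees from the principal
axis, with the Watson axis moments c2 = <cos^2>, c4 = <cos^4> tied to the
ODF invariant p2, and additionally reports p2.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.utils.validation import check_is_fitted

from .._sph import fibonacci_hemisphere
from ._base import BaseVoxelEstimator
from ._watson import P2_MAX, watson_curves
from .dki import apparent_diffusion, apparent_kurtosis, dki_fit

__all__ = ["WMTI", "WatsonWMTI"]

# quadratic-form design for fitting a symmetric tensor to a(n) = n.T.n
_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1, 1, 1, 2, 2, 2], dtype=float)


def _quadratic_design(dirs: np.ndarray) -> np.ndarray:
    return np.stack([m * dirs[:, i] * dirs[:, j]
                     for (i, j), m in zip(_D_IDX, _D_MULT)], axis=1)


def _tensors_from_directional(values: np.ndarray,
                              design_pinv: np.ndarray) -> np.ndarray:
    """LS-fit symmetric tensors to per-direction values (n_vox, n_dirs)."""
    comp = values @ design_pinv.T  # (n_vox, 6)
    t = np.zeros(values.shape[:1] + (3, 3))
    for c, (i, j) in enumerate(_D_IDX):
        t[:, i, j] = comp[:, c]
        t[:, j, i] = comp[:, c]
    return t


class WMTI(BaseVoxelEstimator):
    """Classic WMTI: aligned-fiber SM estimates from DKI, Da <= De_par."""

    estimated_parameters = ("f", "da", "depar", "deperp")

    def __init__(self, protocol=None, n_grid: int = 128):
        self.protocol = protocol
        self.n_grid = n_grid

    def fit(self, X=None, y=None) -> "WMTI":
        self._check_protocol()
        if self.n_grid < 100:
            raise ValueError("direction grid must have >= 100 points")
        self.grid_ = fibonacci_hemisphere(self.n_grid)
        q = _quadratic_design(self.grid_)
        self.design_pinv_ = np.linalg.pinv(q)
        return self

    def predict(self, signals: np.ndarray) -> "pd.DataFrame":  # noqa: F821
        check_is_fitted(self, "grid_")
        proto = self._check_protocol()
        fit = dki_fit(np.atleast_2d(signals), proto)
        dn = apparent_diffusion(fit, self.grid_)
        kn = np.clip(apparent_kurtosis(fit, self.grid_), 0.0, None)

        f = np.max(kn / (kn + 3.0), axis=1)
        flagged = (f <= 1e-6) | (f >= 1.0 - 1e-6)
        f_safe = np.clip(f, 1e-6, 1.0 - 1e-6)[:, None]

        # minus branch (intra) / plus branch (extra): Da <= D(n) <= De(n)
        da_n = dn * (1.0 - np.sqrt(kn * (1.0 - f_safe) / (3.0 * f_safe)))
        de_n = dn * (1.0 + np.sqrt(kn * f_safe / (3.0 * (1.0 - f_safe))))

        t_intra = _tensors_from_directional(da_n, self.design_pinv_)
        t_extra = _tensors_from_directional(de_n, self.design_pinv_)
        da = np.trace(t_intra, axis1=1, axis2=2)
        ev = np.linalg.eigvalsh(t_extra)  # ascending
        depar = ev[:, 2]
        deperp = ev[:, :2].mean(axis=1)
        flagged |= (da < 0) | (deperp < 0) | ~np.isfinite(da)
        return self._wrap(
            {"f": f, "da": da, "depar": depar, "deperp": deperp}, flagged)


_WW_STARTS = [
    (0.5, 1.5, 0.5, 0.8, 0.5),
    (0.3, 1.0, 1.0, 0.4, 0.3),
    (0.7, 2.0, 0.3, 1.2, 0.7),
    (0.4, 1.8, 0.1, 0.9, 0.8),
    (0.6, 1.2, 0.8, 0.6, 0.4),
]


class WatsonWMTI(BaseVoxelEstimator):
    """Watson-ODF WMTI variant with the Da >= De_par branch (experimental).

    Parametrized as (f, De_par, Da - De_par >= 0, De_par - De_perp >= 0,
    p2) so the branch and the physical ordering hold by construction.
    """

    estimated_parameters = ("f", "da", "depar", "deperp", "p2")

    def __init__(self, protocol=None, n_ring: int = 16, n_starts: int = 5,
                 tol: float = 1e-10):
        self.protocol = protocol
        self.n_ring = n_ring
        self.n_starts = n_starts
        self.tol = tol

    def fit(self, X=None, y=None) -> "WatsonWMTI":
        self._check_protocol()
        curves = watson_curves()
        self.c2_of_p2_ = curves["c2_of_p2"]
        self.c4_of_p2_ = curves["c4_of_p2"]
        return self

    # -- model moments -----------------------------------------------------
    @staticmethod
    def _axis_moments(c2, c4, theta):
        """Watson averages q2 = <(n.g)^2>, q4 = <(n.g)^4> at polar angle."""
        ct2 = np.cos(theta) ** 2
        st2 = 1.0 - ct2
        q2 = c2 * ct2 + 0.5 * (1.0 - c2) * st2
        q4 = (c4 * ct2**2 + 3.0 * (c2 - c4) * ct2 * st2
              + 0.375 * (1.0 - 2.0 * c2 + c4) * st2**2)
        return q2, q4

    def _model(self, x, thetas):
        f, depar, da_exc, dperp_def, p2 = x
        da = depar + da_exc
        deperp = max(depar - dperp_def, 0.0)
        delta = depar - deperp
        c2 = float(self.c2_of_p2_(p2))
        c4 = float(self.c4_of_p2_(p2))
        q2, q4 = self._axis_moments(c2, c4, thetas)
        d = f * da * q2 + (1.0 - f) * (deperp + delta * q2)
        m2 = (f * da**2 * q4
              + (1.0 - f) * (deperp**2 + 2.0 * deperp * delta * q2
                             + delta**2 * q4))
        k = 3.0 * (m2 - d**2) / np.where(d**2 > 1e-12, d**2, 1e-12)
        return d, k

    # -- per-voxel observables from DKI ------------------------------------
    def _observables(self, fit) -> tuple[np.ndarray, np.ndarray]:
        n = len(fit)
        evals, evecs = np.linalg.eigh(fit.d)
        axis = evecs[:, :, 2]  # principal eigenvector
        # orthonormal frame per voxel
        helper = np.where(np.abs(axis[:, [0]]) < 0.9,
                          np.tile([1.0, 0.0, 0.0], (n, 1)),
                          np.tile([0.0, 1.0, 0.0], (n, 1)))
        e1 = np.cross(axis, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(axis, e1)
        phis = 2.0 * np.pi * np.arange(self.n_ring) / self.n_ring
        obs = np.empty((n, 5))
        obs[:, 0] = np.einsum("ni,nij,nj->n", axis, fit.d, axis)  # D_par
        obs[:, 1] = (np.trace(fit.d, axis1=1, axis2=2) - obs[:, 0]) / 2.0
        for i in range(n):  # per-voxel rings (K is rotation dependent)
            sub = type(fit)(fit.s0[i:i + 1], fit.d[i:i + 1],
                            fit.w[i:i + 1], fit.md[i:i + 1])
            ring90 = (np.outer(np.cos(phis), e1[i])
                      + np.outer(np.sin(phis), e2[i]))
            ring45 = (ring90 + axis[i]) / np.sqrt(2.0)
            obs[i, 2] = apparent_kurtosis(sub, axis[i][None])[0, 0]
            obs[i, 3] = apparent_kurtosis(sub, ring45).mean()
            obs[i, 4] = apparent_kurtosis(sub, ring90).mean()
        return obs, axis

    def predict(self, signals: np.ndarray) -> "pd.DataFrame":  # noqa: F821
        check_is_fitted(self, "c2_of_p2_")
        proto = self._check_protocol()
        fit = dki_fit(np.atleast_2d(signals), proto)
        obs, _ = self._observables(fit)
        thetas = np.array([0.0, np.pi / 4.0, np.pi / 2.0])
        n = len(fit)
        out = np.full((n, 5), np.nan)
        flagged = np.zeros(n, dtype=bool)
        bounds = ([1e-3, 0.0, 0.0, 0.0, 0.0],
                  [1.0 - 1e-3, 3.0, 3.0, 3.0, P2_MAX])
        for i in range(n):
            target = obs[i]

            def resid(x):
                d, k = self._model(x, thetas)
                return np.concatenate([[d[0] - target[0], d[2] - target[1]],
                                       k - target[2:]])

            best_cost, best_x = np.inf, None
            for x0 in _WW_STARTS[:self.n_starts]:
                try:
                    sol = least_squares(resid, x0, bounds=bounds,
                                        xtol=self.tol, ftol=self.tol,
                                        gtol=self.tol)
                except Exception:
                    continue
                if sol.cost < best_cost:
                    best_cost, best_x = sol.cost, sol.x
            if best_x is None or not np.isfinite(best_cost):
                flagged[i] = True
                continue
            f, depar, da_exc, dperp_def, p2 = best_x
            out[i] = [f, depar + da_exc, depar,
                      max(depar - dperp_def, 0.0), p2]
        return self._wrap(
            {"f": out[:, 0], "da": out[:, 1], "depar": out[:, 2],
             "deperp": out[:, 3], "p2": out[:, 4]}, flagged)
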