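"""NODDI-style constrained estimator.

Constraints: Da = De_par fixed at 1.7 um^2/ms, tortuosity
De_perp = De_par * (1 - f), Watson ODF.  Free parameters: the axonal water
fraction f and the Watson concentration kappa (reported through the ODF
invariant p2).  The fiber axis is a nuisance parameter: the fit is carried
out on the per-shell rotational invariants S_l(b), which are independent of
the axis, so the model reduces to

    S_l(b) = p_l(kappa) * K_l(b; f),   l = 0, 2, 4, both shells,

solved per voxel by bounded nonlinear least squares with multiple starts
(one seeded from a vectorized coarse grid search, the rest stratified).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from sklearn.utils.validation import check_is_fitted

from ..forward import KernelParams, kernel_projection
from ._base import BaseVoxelEstimator, signal_features
from ._watson import P2_MAX, watson_curves

__all__ = ["NODDI"]

_EXTRA_STARTS = [(0.2, 0.2), (0.7, 0.2), (0.2, 0.7), (0.7, 0.7)]


class NODDI(BaseVoxelEstimator):
    """Watson-ODF, fixed-diffusivity (1.7 um^2/ms), tortuosity-constrained
    Standard Model estimator; returns f and p2 only."""

    estimated_parameters = ("f", "p2")

    def __init__(self, protocol=None, fixed_d: float = 1.7,
                 n_starts: int = 5, lmax: int = 4, grid_size: int = 41,
                 tol: float = 1e-10):
        self.protocol = protocol
        self.fixed_d = fixed_d
        self.n_starts = n_starts
        self.lmax = lmax
        self.grid_size = grid_size
        self.tol = tol

    def fit(self, X=None, y=None) -> "NODDI":
        """Precompute K_l(b; f) splines and the Watson (p2, p4) curve."""
        proto = self._check_protocol()
        ls = list(range(0, self.lmax + 1, 2))
        fgrid = np.linspace(0.0, 1.0, 201)
        params = KernelParams(
            f=fgrid, da=self.fixed_d, depar=self.fixed_d,
            deperp=self.fixed_d * (1.0 - fgrid))
        self.k_splines_ = {
            b: {l: CubicSpline(fgrid, kernel_projection(params, b, l))
                for l in ls}
            for b in proto.shell_bvals}
        self.p4_of_p2_ = watson_curves()["p4_of_p2"]
        self.kappa_of_p2_ = watson_curves()["kappa_of_p2"]
        self.ls_ = ls
        return self

    def _model(self, f, p2):
        """Model invariants |p_l K_l|, shape broadcast(f, p2) + (6,).

        Measured rotational invariants are root-sum-square magnitudes, so
        the model takes the absolute value (K_2, K_4 are negative for
        decaying kernels).
        """
        f = np.asarray(f, dtype=float)
        p2 = np.asarray(p2, dtype=float)
        pl = {0: np.ones_like(p2), 2: p2, 4: self.p4_of_p2_(p2)}
        cols = [np.abs(pl[l] * self.k_splines_[b][l](f))
                for b in sorted(self.k_splines_) for l in self.ls_]
        return np.stack(np.broadcast_arrays(*cols), axis=-1)

    def predict(self, signals: np.ndarray) -> "pd.DataFrame":  # noqa: F821
        check_is_fitted(self, "k_splines_")
        proto = self._check_protocol()
        feats = signal_features(signals, proto, lmax=self.lmax)
        n = feats.shape[0]

        # vectorized coarse grid search for the seeded start
        g = self.grid_size
        fg, pg = np.meshgrid(np.linspace(0.01, 0.99, g),
                             np.linspace(0.0, P2_MAX, g), indexing="ij")
        grid_model = self._model(fg.ravel(), pg.ravel())  # (g*g, 6)
        sse = (np.sum(feats**2, axis=1)[:, None]
               - 2.0 * feats @ grid_model.T
               + np.sum(grid_model**2, axis=1)[None, :])
        best = np.argmin(sse, axis=1)
        seeds = np.stack([fg.ravel()[best], pg.ravel()[best]], axis=1)

        starts_extra = _EXTRA_STARTS[:max(self.n_starts - 1, 0)]
        fhat = np.empty(n)
        p2hat = np.empty(n)
        flagged = np.zeros(n, dtype=bool)
        bounds = ([0.0, 0.0], [1.0, P2_MAX])
        for i in range(n):
            target = feats[i]

            def resid(x):
                return self._model(x[0], x[1]) - target

            best_cost, best_x = np.inf, None
            for x0 in [tuple(seeds[i])] + starts_extra:
                try:
                    sol = least_squares(resid, x0, bounds=bounds,
                                        xtol=self.tol, ftol=self.tol,
                                        gtol=self.tol)
                except Exception:
                    continue
                if sol.cost < best_cost:
                    best_cost, best_x = sol.cost, sol.x
            if best_x is None:
                flagged[i] = True
                fhat[i], p2hat[i] = np.nan, np.nan
            else:
                fhat[i], p2hat[i] = best_x
        return self._wrap({"f": fhat, "p2": p2hat}, flagged)
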