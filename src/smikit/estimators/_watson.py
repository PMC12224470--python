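"""Cached Watson-ODF dispersion curves shared by the constrained estimators.

A Watson ODF traces a one-parameter family in the (p2, p4) invariant plane;
estimators that assume Watson dispersion (NODDI, W-WMTI) only need the
curve p4 = w(p2) and the inverse map p2 -> kappa.  Both are tabulated once
on a log-spaced kappa grid and interpolated monotonically.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from ..forward import watson_cos_moments, watson_invariants

__all__ = ["watson_curves", "P2_MAX"]

_cache: dict[str, object] = {}

_KAPPA_GRID = np.concatenate([[0.0], np.logspace(-2, 4, 140)])
P2_MAX = 0.995  # ~ kappa = 1e4; optimizers stay below the delta limit


def watson_curves() -> dict[str, PchipInterpolator]:
    """Monotone interpolants: p4_of_p2, kappa_of_p2, c2_of_p2, c4_of_p2."""
    if not _cache:
        inv = watson_invariants(_KAPPA_GRID, lmax=4)
        p2, p4 = np.asarray(inv[2]), np.asarray(inv[4])
        c2, c4 = watson_cos_moments(_KAPPA_GRID)
        # p2 is strictly increasing in kappa; guard against roundoff ties
        keep = np.concatenate([[True], np.diff(p2) > 1e-12])
        p2k, p4k = p2[keep], p4[keep]
        _cache["p4_of_p2"] = PchipInterpolator(p2k, p4k, extrapolate=True)
        _cache["kappa_of_p2"] = PchipInterpolator(
            p2k, _KAPPA_GRID[keep], extrapolate=True)
        _cache["c2_of_p2"] = PchipInterpolator(p2k, c2[keep], extrapolate=True)
        _cache["c4_of_p2"] = PchipInterpolator(p2k, c4[keep], extrapolate=True)
    return _cache  # type: ignore[return-value]
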