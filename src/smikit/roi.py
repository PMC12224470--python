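"""ROI-level statistics: outlier exclusion, white-matter masking by
fractional anisotropy, and exponential trend fitting.

These utilities mirror the post-processing applied to parameter maps in
clinical analyses: per-ROI voxel values are cleaned in two passes
(physically impossible values first, then a single +/-2 sigma cut about the
surviving mean), white matter is delineated by FA > 0.2, and developmental
time courses are summarized by the time constant of an exponential
A exp(-t/tau) + B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import t as student_t

from .estimators.dki import fa_from_tensors
from .forward import D0_FREE_WATER

__all__ = ["ROISample", "exclude_outliers", "fa_mask",
           "ExpFitResult", "fit_exponential", "PHYSICAL_BOUNDS"]

PHYSICAL_BOUNDS = {
    "f": (0.0, 1.0), "p2": (0.0, 1.0), "p4": (0.0, 1.0),
    "da": (0.0, D0_FREE_WATER), "depar": (0.0, D0_FREE_WATER),
    "deperp": (0.0, D0_FREE_WATER),
}


@dataclass
class ROISample:
    """Voxelwise values of one parameter within one ROI."""

    values: np.ndarray
    parameter: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("ROI sample is empty")
        if self.parameter not in PHYSICAL_BOUNDS:
            raise ValueError(f"unknown parameter {self.parameter!r}; "
                             f"expected one of {sorted(PHYSICAL_BOUNDS)}")


def exclude_outliers(sample: ROISample) -> tuple[ROISample, dict]:
    """Two-pass outlier exclusion for an ROI sample.

    Pass 1 drops physically impossible values (outside the parameter's
    bounds); pass 2 computes mean and sigma on the survivors and drops
    values outside mean +/- 2 sigma, applied once (non-iterative).
    Returns the filtered sample and per-stage exclusion counts.
    """
    if sample.values.size < 5:
        raise ValueError("need >= 5 values for outlier exclusion")
    lo, hi = PHYSICAL_BOUNDS[sample.parameter]
    v = sample.values
    physical = v[np.isfinite(v) & (v >= lo) & (v <= hi)]
    n_unphysical = v.size - physical.size
    if physical.size == 0:
        raise ValueError("all ROI values are unphysical")
    mean, sigma = physical.mean(), physical.std()
    keep = np.abs(physical - mean) <= 2.0 * sigma
    survivors = physical[keep]
    counts = {"unphysical": int(n_unphysical),
              "two_sigma": int(physical.size - survivors.size),
              "kept": int(survivors.size)}
    return ROISample(survivors, sample.parameter), counts


def fa_mask(tensors: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Binary white-matter mask: FA strictly greater than ``threshold``.

    ``tensors`` is (..., 3, 3); non-finite tensors are excluded.
    """
    fa = np.asarray(fa_from_tensors(tensors))
    shape = np.asarray(tensors).shape[:-2]
    fa = fa.reshape(shape) if shape else fa
    return np.where(np.isfinite(fa), fa > threshold, False)


@dataclass
class ExpFitResult:
    """Exponential trend fit y = A exp(-t/tau) + B; tau reported as |tau|."""

    a: float
    tau: float
    b: float
    ci_a: tuple[float, float]
    ci_tau: tuple[float, float]
    ci_b: tuple[float, float]
    converged: bool


_TAU_STARTS = (0.1, 0.5, 1.0, 2.0, 5.0)


def fit_exponential(t: np.ndarray, y: np.ndarray,
                    tau_starts=_TAU_STARTS) -> ExpFitResult:
    """Nonlinear least-squares fit of A exp(-t/tau) + B with multi-start.

    t is in years.  95% confidence intervals come from the Jacobian-based
    covariance with Student-t quantiles (n - 3 dof).  Growing data (raw
    tau < 0) is handled by the sign of A; tau is reported as |tau|.  A fit
    with an unidentifiable tau (degenerate Jacobian) is flagged
    unconverged.
    """
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if t.size != y.size or t.size < 4:
        raise ValueError("need >= 4 matched (t, y) points")
    if np.ptp(t) <= 0:
        raise ValueError("t values must have nonzero spread")

    def model(p, tt):
        return p[0] * np.exp(-tt / p[1]) + p[2]

    spread = np.ptp(y) if np.ptp(y) > 0 else 1.0
    best = None
    for tau0 in tau_starts:
        p0 = (y[np.argmin(t)] - y[np.argmax(t)], tau0, y[np.argmax(t)])
        try:
            sol = least_squares(lambda p: model(p, t) - y, p0,
                                bounds=([-np.inf, 1e-6, -np.inf],
                                        [np.inf, np.inf, np.inf]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return ExpFitResult(np.nan, np.nan, np.nan, (np.nan, np.nan),
                            (np.nan, np.nan), (np.nan, np.nan), False)
    p = best.x
    dof = max(t.size - 3, 1)
    rss = 2.0 * best.cost
    jtj = best.jac.T @ best.jac
    converged = bool(best.success)
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.inf)
        converged = False
    # identifiability check: amplitude indistinguishable from flat data
    if abs(p[0]) < 1e-10 * spread or not np.all(np.isfinite(se)):
        converged = False
    q = student_t.ppf(0.975, dof)
    cis = [(p[i] - q * se[i], p[i] + q * se[i]) for i in range(3)]
    # tau is constrained positive in the fit; clip its CI at zero
    ci_tau = (max(cis[1][0], 0.0), cis[1][1])
    return ExpFitResult(p[0], abs(p[1]), p[2], cis[0], ci_tau, cis[2],
                        converged)
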