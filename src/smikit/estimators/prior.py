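"""Gaussian parameter prior used to train the machine-learning estimator.

The prior over theta = {f, Da, De_par, De_perp, p2} is an independent
Gaussian truncated to the physical box (fractions and ODF invariants in
[0, 1], diffusivities in [0, 3] um^2/ms) with the additional constraint
De_perp <= De_par, both enforced by rejection.  p4 is tied to p2 through a
uniform ratio p4/p2 reflecting histological ODF shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..forward import D0_FREE_WATER

__all__ = ["PriorSpec", "sample_prior", "PARAM_NAMES", "TARGET_NAMES"]

PARAM_NAMES = ("f", "da", "depar", "deperp", "p2")
TARGET_NAMES = ("f", "da", "depar", "deperp", "p2", "p4")

#: reference prior moments for {f, Da, De_par, De_perp, p2}
DEFAULT_MEAN = (0.5, 2.0, 2.0, 0.7, 0.45)
DEFAULT_VARIANCE = (0.06, 1.0, 1.0, 0.1, 0.06)


@dataclass(frozen=True)
class PriorSpec:
    """Truncated-Gaussian prior over {f, da, depar, deperp, p2}.

    ``variance`` is a variance (not a standard deviation).  ``bounds`` maps
    parameter name -> (lo, hi); defaults are the physical box.
    """

    mean: tuple[float, ...] = DEFAULT_MEAN
    variance: tuple[float, ...] = DEFAULT_VARIANCE
    p4_ratio_range: tuple[float, float] = (0.75, 0.85)
    bounds: dict = field(default_factory=lambda: {
        "f": (0.0, 1.0),
        "da": (0.0, D0_FREE_WATER),
        "depar": (0.0, D0_FREE_WATER),
        "deperp": (0.0, D0_FREE_WATER),
        "p2": (0.0, 1.0),
    })

    def __post_init__(self):
        if len(self.mean) != 5 or len(self.variance) != 5:
            raise ValueError("mean and variance must have 5 entries "
                             "(f, da, depar, deperp, p2)")
        if any(v <= 0 for v in self.variance):
            raise ValueError("variances must be positive")
        for name, mu in zip(PARAM_NAMES, self.mean):
            lo, hi = self.bounds[name]
            if not lo <= mu <= hi:
                raise ValueError(f"prior mean for {name} ({mu}) is outside "
                                 f"its physical bounds [{lo}, {hi}]")

    def with_mean(self, **updates: float) -> "PriorSpec":
        """Copy of the prior with selected mean entries replaced."""
        mean = list(self.mean)
        for name, value in updates.items():
            mean[PARAM_NAMES.index(name)] = value
        return PriorSpec(tuple(mean), self.variance, self.p4_ratio_range,
                         dict(self.bounds))


def sample_prior(prior: PriorSpec, n: int,
                 rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Draw n ground-truth parameter rows from the truncated prior.

    Returns a DataFrame with columns f, da, depar, deperp, p2, p4.  Draws
    violating the physical bounds or De_perp <= De_par are rejected and
    redrawn; p4 = rho * p2 with rho ~ U(p4_ratio_range).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    mean = np.asarray(prior.mean)
    sd = np.sqrt(np.asarray(prior.variance))
    lo = np.array([prior.bounds[p][0] for p in PARAM_NAMES])
    hi = np.array([prior.bounds[p][1] for p in PARAM_NAMES])
    rows = np.empty((0, 5))
    while len(rows) < n:
        batch = max(n - len(rows), 1024)
        draw = mean + sd * rng.standard_normal((batch, 5))
        ok = np.all((draw >= lo) & (draw <= hi), axis=1)
        ok &= draw[:, 3] <= draw[:, 2]  # De_perp <= De_par
        rows = np.vstack([rows, draw[ok]])
    rows = rows[:n]
    rho = rng.uniform(*prior.p4_ratio_range, size=n)
    table = pd.DataFrame(rows, columns=list(PARAM_NAMES))
    table["p4"] = rho * table["p2"]
    return table
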