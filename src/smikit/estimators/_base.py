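"""Shared estimator machinery: feature extraction and the EstimateSet contract.

Every voxel estimator is a scikit-learn style object: hyper-parameters in
``__init__``, precomputation in ``fit``, and ``predict(signals)`` returning
a DataFrame holding exactly the parameters that estimator actually
estimates (constrained parameters are left out) plus a boolean ``flagged``
column marking voxels whose fit failed and should be excluded downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ..forward import fit_sh, rotational_invariants
from ..protocol import Protocol

__all__ = ["signal_features", "BaseVoxelEstimator", "FEATURE_NAMES"]


def feature_names(protocol: Protocol, lmax: int = 4) -> list[str]:
    return [f"S{l}(b={b:g})" for b in protocol.shell_bvals
            for l in range(0, lmax + 1, 2)]


FEATURE_NAMES = feature_names  # legacy alias


def signal_features(signals: np.ndarray, protocol: Protocol,
                    lmax: int = 4) -> np.ndarray:
    """Rotational-invariant feature matrix (n_vox, n_shells * n_l).

    Per-shell invariants S_l(b), l = 0..lmax even, normalized by the
    measured b=0 mean so the proton density drops out; column order is
    shell-major: [S0(b1), S2(b1), S4(b1), S0(b2), ...].
    """
    fit = fit_sh(signals, protocol, lmax=lmax)
    return rotational_invariants(fit, lmax=lmax, normalize=True).features()


class BaseVoxelEstimator(BaseEstimator):
    """Base for per-voxel Standard Model estimators."""

    #: names of the parameters this estimator actually estimates
    estimated_parameters: tuple[str, ...] = ()

    def _check_protocol(self) -> Protocol:
        if getattr(self, "protocol", None) is None:
            raise ValueError(f"{type(self).__name__} requires a protocol")
        proto = self.protocol
        if len(proto.nonzero_shells) < 1:
            raise ValueError("protocol has no nonzero shell")
        return proto

    def _wrap(self, columns: dict[str, np.ndarray],
              flagged: np.ndarray) -> pd.DataFrame:
        out = pd.DataFrame({k: np.asarray(v, dtype=float)
                            for k, v in columns.items()})
        out["flagged"] = np.asarray(flagged, dtype=bool)
        out.attrs["estimator"] = type(self).__name__
        return out

    def fit_predict(self, signals: np.ndarray) -> pd.DataFrame:
        return self.fit().predict(signals)
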