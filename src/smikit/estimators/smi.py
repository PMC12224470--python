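"""Standard Model Imaging: polynomial-regression estimation of SM parameters.

SMI maps the six per-shell rotational invariants {S0, S2, S4} x {b1, b2}
(normalized by the b=0 signal) to the Standard Model parameters
{f, Da, De_par, De_perp, p2, p4} with one third-order polynomial regression
per parameter.  The regressions are trained on synthetic signals whose
ground truths are drawn from a truncated Gaussian prior; the prior acts as
a soft regularizer (the training distribution) instead of hard parameter
constraints.  Training noise matches the intended measurement noise so the
regression learns the optimal bias-variance trade-off at that SNR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import PolynomialFeatures
from sklearn.utils.validation import check_is_fitted

from ..forward import D0_FREE_WATER, KernelParams, add_noise, synthesize_zonal
from ..protocol import Protocol
from .._sph import random_unit_vectors
from ._base import BaseVoxelEstimator, signal_features
from .prior import PriorSpec, TARGET_NAMES, sample_prior

__all__ = ["build_training_set", "SMIRegressor", "SMI", "train_smi"]

_BOUNDS = {
    "f": (0.0, 1.0), "p2": (0.0, 1.0), "p4": (0.0, 1.0),
    "da": (0.0, D0_FREE_WATER), "depar": (0.0, D0_FREE_WATER),
    "deperp": (0.0, D0_FREE_WATER),
}


def build_training_set(prior: PriorSpec, protocol: Protocol, snr: float,
                       n: int, rng: np.random.Generator | int | None = None,
                       lmax: int = 4) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize a (features, targets) training set from the prior.

    Each draw: sample {f, Da, De_par, De_perp, p2, p4} and a uniformly
    random fiber axis, synthesize noise-free zonal-ODF signals on the
    protocol, add Gaussian noise at ``snr`` (sigma = s0/snr), then compress
    to b0-normalized rotational invariants.
    """
    if len(protocol.nonzero_shells) < 2:
        raise ValueError("training requires a protocol with >= 2 shells")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    targets = sample_prior(prior, n, rng)
    axes = random_unit_vectors(n, rng)
    params = KernelParams(
        f=targets["f"].to_numpy(), da=targets["da"].to_numpy(),
        depar=targets["depar"].to_numpy(),
        deperp=targets["deperp"].to_numpy())
    signals = synthesize_zonal(
        params, {2: targets["p2"].to_numpy(), 4: targets["p4"].to_numpy()},
        axes, protocol, lmax=lmax)
    if np.isfinite(snr):
        signals = add_noise(signals, snr, rng, model="gaussian")
    features = signal_features(signals, protocol, lmax=lmax)
    return features, targets


class SMIRegressor(BaseEstimator, RegressorMixin):
    """Multi-target polynomial regression (all monomials up to ``degree``).

    Ordinary least squares via SVD; an L2 ridge (``alpha``) is added only
    if the design is numerically rank deficient.
    """

    def __init__(self, degree: int = 3, alpha: float = 1e-8):
        self.degree = degree
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        y2 = y[:, None] if y.ndim == 1 else y
        self.poly_ = PolynomialFeatures(degree=self.degree, include_bias=True)
        phi = self.poly_.fit_transform(X)
        if phi.shape[0] < phi.shape[1]:
            raise np.linalg.LinAlgError(
                f"singular design: {phi.shape[0]} samples for "
                f"{phi.shape[1]} monomials; increase the training size")
        coef, _, rank, _ = np.linalg.lstsq(phi, y2, rcond=None)
        if rank < phi.shape[1]:  # rank-deficient: ridge fallback
            gram = phi.T @ phi + self.alpha * np.eye(phi.shape[1])
            coef = np.linalg.solve(gram, phi.T @ y2)
        self.coef_ = coef
        self.n_features_in_ = X.shape[1]
        self.n_targets_ = y2.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        phi = self.poly_.transform(np.asarray(X, dtype=float))
        out = phi @ self.coef_
        return out[:, 0] if self.n_targets_ == 1 else out


class SMI(BaseVoxelEstimator):
    """Trained SMI estimator for a fixed protocol and noise level.

    Parameters
    ----------
    protocol : Protocol
        Two-shell acquisition the estimator is trained for.
    prior : PriorSpec
        Training prior over {f, Da, De_par, De_perp, p2} (+ p4 ratio).
    snr : float
        Training SNR (Gaussian noise, sigma = s0/snr); use np.inf for a
        noise-free mapping.
    n_training : int
        Number of synthetic training voxels.
    """

    estimated_parameters = TARGET_NAMES

    def __init__(self, protocol: Protocol | None = None,
                 prior: PriorSpec | None = None, snr: float = 25.0,
                 n_training: int = 100_000, degree: int = 3, lmax: int = 4,
                 random_state: int | None = 0):
        self.protocol = protocol
        self.prior = prior
        self.snr = snr
        self.n_training = n_training
        self.degree = degree
        self.lmax = lmax
        self.random_state = random_state

    def fit(self, X=None, y=None) -> "SMI":
        """Synthesize the training set and fit the polynomial regressions."""
        proto = self._check_protocol()
        prior = self.prior if self.prior is not None else PriorSpec()
        rng = np.random.default_rng(self.random_state)
        features, targets = build_training_set(
            prior, proto, self.snr, self.n_training, rng, lmax=self.lmax)
        reg = SMIRegressor(degree=self.degree)
        reg.fit(features, targets[list(TARGET_NAMES)].to_numpy())
        self.regressor_ = reg
        self.prior_ = prior
        self.protocol_hash_ = proto.content_hash()
        self.training_meta_ = {
            "n": self.n_training, "snr": self.snr, "degree": self.degree,
            "seed": self.random_state, "protocol": self.protocol_hash_,
            "prior_mean": list(prior.mean),
            "prior_variance": list(prior.variance),
        }
        return self

    # -- inference ---------------------------------------------------------
    def predict_features(self, features: np.ndarray) -> pd.DataFrame:
        """Estimates from a precomputed invariant feature matrix."""
        check_is_fitted(self, "regressor_")
        raw = self.regressor_.predict(np.asarray(features, dtype=float))
        cols, clips = {}, {}
        for j, name in enumerate(TARGET_NAMES):
            lo, hi = _BOUNDS[name]
            v = raw[:, j]
            clips[name] = int(np.sum((v < lo) | (v > hi)))
            cols[name] = np.clip(v, lo, hi)
        self.clip_counts_ = clips
        return self._wrap(cols, np.zeros(raw.shape[0], dtype=bool))

    def predict(self, signals: np.ndarray,
                protocol: Protocol | None = None) -> pd.DataFrame:
        """Estimates from raw per-volume signals (protocol-hash checked)."""
        check_is_fitted(self, "regressor_")
        proto = protocol if protocol is not None else self.protocol
        if proto.content_hash() != self.protocol_hash_:
            raise ValueError(
                "signals were acquired under a different protocol than the "
                "one this SMI model was trained for")
        return self.predict_features(
            signal_features(signals, proto, lmax=self.lmax))


    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Serialize the trained model (JSON: metadata + coefficients)."""
        import json
        from pathlib import Path

        check_is_fitted(self, "regressor_")
        doc = {
            "format": "smikit-smi-model",
            "version": 1,
            "training": self.training_meta_,
            "lmax": self.lmax,
            "targets": list(TARGET_NAMES),
            "coefficients": self.regressor_.coef_.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path, protocol: Protocol) -> "SMI":
        """Restore a trained model; ``protocol`` must match the training
        protocol (hash-checked at predict time)."""
        import json
        from pathlib import Path

        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "smikit-smi-model":
            raise ValueError(f"{path} is not an SMI model file")
        meta = doc["training"]
        model = cls(protocol=protocol, snr=meta["snr"],
                    n_training=meta["n"], degree=meta["degree"],
                    lmax=doc["lmax"], random_state=meta["seed"])
        reg = SMIRegressor(degree=meta["degree"])
        coef = np.asarray(doc["coefficients"])
        reg.poly_ = PolynomialFeatures(degree=meta["degree"],
                                       include_bias=True)
        reg.poly_.fit(np.zeros((1, 6)))
        reg.coef_ = coef
        reg.n_features_in_ = 6
        reg.n_targets_ = coef.shape[1]
        model.regressor_ = reg
        model.prior_ = PriorSpec(tuple(meta["prior_mean"]),
                                 tuple(meta["prior_variance"]))
        model.protocol_hash_ = meta["protocol"]
        model.training_meta_ = meta
        return model


def train_smi(features: np.ndarray, targets: pd.DataFrame,
              degree: int = 3) -> SMIRegressor:
    """Fit the bare polynomial regression on an existing training set."""
    y = targets[list(TARGET_NAMES)].to_numpy() if isinstance(
        targets, pd.DataFrame) else np.asarray(targets)
    return SMIRegressor(degree=degree).fit(features, y)
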