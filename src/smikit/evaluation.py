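"""Simulation benchmark: test-set generation, the Sensitivity-Specificity
Matrix (SSM) and the prior-impact matrix.

The SSM of an estimator quantifies how each estimated parameter responds to
each ground-truth parameter over a test distribution:

    S_ij = (<theta_i> / <theta_hat_j>) * d<theta_hat_j> / d theta_i

evaluated as normalized slopes of an ordinary least-squares regression (with
intercept) of each estimate on all ground-truth parameters.  An ideal SSM
is the identity: unit diagonal (full sensitivity) and zero off-diagonals
(no spurious cross-parameter correlations).  The prior-impact matrix P_ij
is the analogous normalized derivative of the mean estimate with respect to
the training-prior mean, obtained by retraining the ML estimator on a sweep
of perturbed priors.

The canonical study conditions: ground truths uniform on the box
[0.3, 1.5, 1.5, 0.4, 0.3] - [0.8, 2.5, 2.5, 1, 0.8] for
{f, Da, De_par, De_perp, p2} (n = 10,000), p4/p2 ~ U(0.75, 0.85), zonal
ODFs with random orientations, two-shell b = 1, 2 ms/um^2 protocol,
Gaussian noise at SNR 25 relative to b=0.  All estimators see the same
noise realization (paired design) so SSM differences between estimators are
not noise-realization artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._sph import random_unit_vectors
from .estimators import (NODDI, SMI, SMT, WMTI, PriorSpec, WatsonWMTI,
                         signal_features)
from .estimators.prior import PARAM_NAMES
from .forward import KernelParams, add_noise, synthesize_zonal
from .protocol import Protocol, default_protocol
from .volumes import VolumeStack

__all__ = [
    "TEST_BOX_LO", "TEST_BOX_HI", "TestSet", "make_test_set",
    "compute_ssm", "PriorImpactMatrix", "prior_impact_sweep",
    "run_benchmark", "synthesize_phantom", "OracleEstimator",
]

log = logging.getLogger(__name__)

#: uniform test box for {f, da, depar, deperp, p2}
TEST_BOX_LO = (0.3, 1.5, 1.5, 0.4, 0.3)
TEST_BOX_HI = (0.8, 2.5, 2.5, 1.0, 0.8)


@dataclass
class TestSet:
    """Ground truths, fiber axes and (noisy) signals of one benchmark run."""

    truth: pd.DataFrame          # columns f, da, depar, deperp, p2, p4
    axes: np.ndarray             # (n, 3) zonal ODF orientations
    signals: np.ndarray          # (n, n_volumes), noisy
    signals_clean: np.ndarray    # noise-free
    protocol: Protocol
    snr: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.truth)


def make_test_set(protocol: Protocol, n: int = 10_000, snr: float = 25.0,
                  lo=TEST_BOX_LO, hi=TEST_BOX_HI,
                  p4_ratio_range=(0.75, 0.85), lmax: int = 4,
                  rng: np.random.Generator | int | None = 0) -> TestSet:
    """Uniform ground-truth draws on [lo, hi] with synthesized noisy signals.

    Zonal ODFs hit (p2, p4) exactly and are randomly oriented; draws with
    De_perp > De_par are rejected (a no-op for the canonical box).  Noise
    is added once so all estimators share the realization.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if not np.all(lo < hi):
        raise ValueError("lo must be elementwise smaller than hi")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    rows = np.empty((0, 5))
    while len(rows) < n:
        draw = rng.uniform(lo, hi, size=(n - len(rows), 5))
        rows = np.vstack([rows, draw[draw[:, 3] <= draw[:, 2]]])
    truth = pd.DataFrame(rows[:n], columns=list(PARAM_NAMES))
    truth["p4"] = rng.uniform(*p4_ratio_range, size=n) * truth["p2"]
    axes = random_unit_vectors(n, rng)
    params = KernelParams(
        f=truth["f"].to_numpy(), da=truth["da"].to_numpy(),
        depar=truth["depar"].to_numpy(), deperp=truth["deperp"].to_numpy())
    clean = synthesize_zonal(
        params, {2: truth["p2"].to_numpy(), 4: truth["p4"].to_numpy()},
        axes, protocol, lmax=lmax)
    noisy = add_noise(clean, snr, rng) if np.isfinite(snr) else clean.copy()
    return TestSet(truth, axes, noisy, clean, protocol, snr,
                   meta={"lo": lo.tolist(), "hi": hi.tolist(), "n": n,
                         "p4_ratio_range": list(p4_ratio_range)})


def compute_ssm(truth: pd.DataFrame, estimates: pd.DataFrame,
                truth_params: tuple[str, ...] = PARAM_NAMES,
                min_valid: int = 100) -> pd.DataFrame:
    """Sensitivity-Specificity Matrix of one estimator's output.

    For each estimated parameter j, fit an OLS regression (with intercept)
    of theta_hat_j on all ground-truth parameters; S_ij is the slope for
    truth parameter i normalized by <theta_i>/<theta_hat_j>.  Rows flagged
    by the estimator are dropped listwise.
    """
    est_cols = [c for c in estimates.columns if c != "flagged"]
    valid = ~estimates.get(
        "flagged", pd.Series(False, index=estimates.index)).to_numpy()
    valid &= np.all(np.isfinite(estimates[est_cols].to_numpy()), axis=1)
    if valid.sum() < min_valid:
        raise ValueError(
            f"only {int(valid.sum())} valid voxels (<{min_valid}); "
            "estimator failed on too many voxels")
    gt = truth.loc[valid, list(truth_params)].to_numpy()
    x = np.column_stack([np.ones(len(gt)), gt])
    cond = np.linalg.cond(x)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"ground-truth design is collinear (cond={cond:.1e})")
    ssm = pd.DataFrame(index=list(truth_params), columns=est_cols,
                       dtype=float)
    gt_means = gt.mean(axis=0)
    for j in est_cols:
        y = estimates.loc[valid, j].to_numpy()
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        mean_est = y.mean()
        denom = mean_est if abs(mean_est) > 1e-12 else np.nan
        ssm[j] = beta[1:] * gt_means / denom
    ssm.attrs["n_valid"] = int(valid.sum())
    ssm.attrs["n_dropped"] = int((~valid).sum())
    return ssm


class OracleEstimator:
    """Ideal estimator returning the ground truth (testing aid)."""

    estimated_parameters = PARAM_NAMES

    def __init__(self, test_set: TestSet):
        self.test_set = test_set

    def fit(self, X=None, y=None):
        return self

    def predict(self, signals=None) -> pd.DataFrame:
        out = self.test_set.truth[list(PARAM_NAMES)].copy()
        out["flagged"] = False
        return out


# ---------------------------------------------------------------------------
# prior impact


@dataclass
class PriorImpactMatrix:
    """Normalized derivatives of mean estimates w.r.t. the prior means.

    ``matrix``: rows = perturbed prior-mean parameter i, columns = estimated
    parameter j.  ``sweep_means`` maps parameter i -> DataFrame indexed by
    the absolute prior mean mu_i with mean estimates per column.
    """

    matrix: pd.DataFrame
    sweep_means: dict[str, pd.DataFrame]
    grid: np.ndarray

    def r_squared(self) -> pd.DataFrame:
        """R^2 of the linear fit <theta_hat_j> vs mu_i for every (i, j)."""
        out = {}
        for pi, table in self.sweep_means.items():
            mu = table.index.to_numpy(dtype=float)
            row = {}
            for j in table.columns:
                y = table[j].to_numpy()
                beta = np.polyfit(mu, y, 1)
                res = y - np.polyval(beta, mu)
                tot = np.sum((y - y.mean()) ** 2)
                row[j] = 1.0 - np.sum(res**2) / tot if tot > 0 else np.nan
            out[pi] = row
        return pd.DataFrame(out).T


def prior_impact_sweep(reference_prior: PriorSpec, protocol: Protocol,
                       snr: float, test_set: TestSet, n_train: int = 50_000,
                       seed: int = 0,
                       grid: np.ndarray | None = None,
                       params: tuple[str, ...] = PARAM_NAMES,
                       estimator_factory=None) -> PriorImpactMatrix:
    """Sweep each prior mean over ``grid`` (fractions of the reference),
    retrain the ML estimator at every grid point, and regress the mean
    estimate on the perturbed prior mean.

    The same training seed is reused at every grid point (paired training
    noise) so the sweep isolates the prior dependence.
    """
    grid = np.arange(0.90, 1.1001, 0.025) if grid is None else np.asarray(grid)
    features = signal_features(test_set.signals, protocol)

    if estimator_factory is None:
        def estimator_factory(prior: PriorSpec):
            return SMI(protocol=protocol, prior=prior, snr=snr,
                       n_training=n_train, random_state=seed).fit()

    ref_mean = dict(zip(PARAM_NAMES, reference_prior.mean))
    truth_means = test_set.truth[list(PARAM_NAMES)].mean()
    sweep_means: dict[str, pd.DataFrame] = {}
    matrix = {}
    for pi in params:
        rows = []
        mus = ref_mean[pi] * grid
        for mu in mus:
            est = estimator_factory(reference_prior.with_mean(**{pi: mu}))
            pred = est.predict_features(features)
            rows.append(pred.drop(columns="flagged").mean())
        table = pd.DataFrame(rows, index=pd.Index(mus, name=f"mu_{pi}"))
        sweep_means[pi] = table
        slopes = {}
        for j in table.columns:
            slope = np.polyfit(mus, table[j].to_numpy(), 1)[0]
            mean_est = table[j].mean()
            denom = mean_est if abs(mean_est) > 1e-12 else np.nan
            slopes[j] = slope * truth_means[pi] / denom
        matrix[pi] = slopes
    return PriorImpactMatrix(pd.DataFrame(matrix).T.loc[list(params)],
                             sweep_means, grid)


# ---------------------------------------------------------------------------
# orchestration


def _build_estimator(name: str, protocol: Protocol, snr: float,
                     n_training: int, seed: int, test_set: TestSet):
    name = name.lower()
    if name == "smi":
        return SMI(protocol=protocol, snr=snr, n_training=n_training,
                   random_state=seed)
    if name == "noddi":
        return NODDI(protocol=protocol)
    if name == "smt":
        return SMT(protocol=protocol)
    if name == "wmti":
        return WMTI(protocol=protocol)
    if name == "wwmti":
        return WatsonWMTI(protocol=protocol)
    if name == "oracle":
        return OracleEstimator(test_set)
    raise ValueError(f"unknown estimator {name!r}")


def run_benchmark(config: dict, outdir: str | Path | None = None) -> dict:
    """Run the full simulation benchmark described by ``config``.

    config keys (all optional): estimators (default all), n, snr, seed,
    n_training, protocol (a Protocol; default two-shell clinical), heatmap.
    Returns a report dict; when ``outdir`` is given, writes
    ``ssm_<estimator>.csv``, ``report.json`` and optional PNG heatmaps.
    """
    estimators = config.get("estimators",
                            ["smi", "noddi", "smt", "wmti"])
    n = int(config.get("n", 10_000))
    snr = float(config.get("snr", 25.0))
    seed = int(config.get("seed", 0))
    n_training = int(config.get("n_training", 100_000))
    protocol = config.get("protocol") or default_protocol(seed=seed)
    test_set = make_test_set(protocol, n=n, snr=snr, rng=seed)

    report: dict = {
        "config": {"estimators": list(estimators), "n": n, "snr": snr,
                   "seed": seed, "n_training": n_training,
                   "protocol_hash": protocol.content_hash()},
        "versions": _versions(),
        "estimators": {},
    }
    ssms: dict[str, pd.DataFrame] = {}
    for name in estimators:
        est = _build_estimator(name, protocol, snr, n_training, seed,
                               test_set)
        try:
            estimates = est.fit().predict(test_set.signals)
            frac_flagged = float(estimates["flagged"].mean())
            if frac_flagged > 0.20:
                raise RuntimeError(
                    f"{name} failed on {frac_flagged:.0%} of voxels")
            ssm = compute_ssm(test_set.truth, estimates)
        except Exception as exc:
            log.error("estimator %s failed: %s", name, exc)
            report["estimators"][name] = {"status": "failed",
                                          "error": str(exc)}
            continue
        ssms[name] = ssm
        report["estimators"][name] = {
            "status": "ok",
            "columns": list(ssm.columns),
            "n_valid": ssm.attrs["n_valid"],
            "n_dropped": ssm.attrs["n_dropped"],
            "ssm": ssm.round(10).to_dict(),
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, ssm in ssms.items():
            ssm.to_csv(outdir / f"ssm_{name}.csv", float_format="%.10g")
            if config.get("heatmap"):
                _heatmap(ssm, name, outdir / f"ssm_{name}.png")
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
    report["_ssms"] = ssms
    return report


def _versions() -> dict:
    import numpy
    import scipy
    import sklearn

    import smikit

    return {"smikit": smikit.__version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__}


def _heatmap(ssm: pd.DataFrame, name: str, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is an optional extra
        return
    fig, ax = plt.subplots(figsize=(1.2 + ssm.shape[1], 4))
    im = ax.imshow(ssm.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(ssm.shape[1]), ssm.columns)
    ax.set_yticks(range(ssm.shape[0]), ssm.index)
    ax.set_title(f"SSM: {name}")
    for (i, j), v in np.ndenumerate(ssm.to_numpy()):
        ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# phantom


def synthesize_phantom(test_set: TestSet,
                       shape: tuple[int, int, int] = (22, 22, 21)
                       ) -> tuple[VolumeStack, pd.DataFrame]:
    """Pack test-set signals into a 4D volume with a voxel lookup table.

    Voxels beyond the test set are zero-filled background.  The lookup
    table maps each test row to its (i, j, k) voxel.
    """
    n = len(test_set)
    n_slots = int(np.prod(shape))
    if n_slots < n:
        raise ValueError(f"shape {shape} holds {n_slots} voxels < {n} rows")
    data = np.zeros((n_slots, test_set.signals.shape[1]))
    data[:n] = test_set.signals
    data = data.reshape(*shape, -1)
    ijk = np.stack(np.unravel_index(np.arange(n), shape), axis=1)
    lookup = pd.DataFrame(ijk, columns=["i", "j", "k"])
    lookup["row"] = np.arange(n)
    return VolumeStack(data), lookup
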