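"""Acquisition protocols: b-values, gradient directions, shell structure.

b-values are expressed in ms/um^2 everywhere inside the package; the
conversion from the s/mm^2 convention of FSL bval files (divide by 1000)
happens only at the file boundary.  Gradient directions are unit vectors;
b=0 volumes may carry a zero vector.  Directions are treated as axially
symmetric (g and -g are equivalent) since only even-degree spherical
harmonics enter the signal model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._sph import fibonacci_hemisphere, random_rotation

__all__ = ["Protocol", "ProtocolError", "read_gradient_table", "default_protocol"]

DEFAULT_SHELL_TOL = 0.1  # ms/um^2


class ProtocolError(ValueError):
    """Malformed gradient table or protocol."""


@dataclass(frozen=True)
class Protocol:
    """Per-volume b-values (ms/um^2) and unit gradient directions.

    Volumes are grouped into shells by clustering b-values within
    ``shell_tol``; the shell with nominal b below the tolerance is the b=0
    shell.  At least one b=0 volume and one nonzero shell are required.
    """

    bvals: np.ndarray
    dirs: np.ndarray
    shell_tol: float = DEFAULT_SHELL_TOL
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        dirs = np.asarray(self.dirs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "dirs", dirs)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ProtocolError("dirs must have shape (n_volumes, 3)")
        if len(bvals) != len(dirs):
            raise ProtocolError(
                f"bval/bvec length mismatch: {len(bvals)} vs {len(dirs)}")
        if np.any(bvals < 0):
            raise ProtocolError("negative b-value in gradient table")
        norms = np.linalg.norm(dirs, axis=1)
        nonzero = bvals > self.shell_tol
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
            raise ProtocolError("non-unit gradient direction on a nonzero shell")
        if not np.any(~nonzero):
            raise ProtocolError("protocol has no b=0 volume")
        if not np.any(nonzero):
            raise ProtocolError("protocol has no nonzero shell")

    # -- shell structure ---------------------------------------------------
    @property
    def shells(self) -> dict[float, np.ndarray]:
        """Mapping nominal shell b-value -> volume indices (b=0 included)."""
        order = np.argsort(self.bvals)
        groups: list[list[int]] = []
        last_b = None
        for idx in order:
            b = self.bvals[idx]
            if last_b is None or b - last_b > self.shell_tol:
                groups.append([idx])
            else:
                groups[-1].append(idx)
            last_b = b
        out: dict[float, np.ndarray] = {}
        for g in groups:
            nominal = float(np.round(np.mean(self.bvals[g]), 6))
            if nominal <= self.shell_tol:
                nominal = 0.0
            out[nominal] = np.array(sorted(g))
        return out

    @property
    def b0_indices(self) -> np.ndarray:
        return self.shells.get(0.0, np.array([], dtype=int))

    @property
    def nonzero_shells(self) -> dict[float, np.ndarray]:
        return {b: idx for b, idx in self.shells.items() if b > 0}

    @property
    def shell_bvals(self) -> np.ndarray:
        """Sorted nominal b-values of the nonzero shells."""
        return np.array(sorted(self.nonzero_shells))

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    # -- identity ----------------------------------------------------------
    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.round(self.bvals, 6).tobytes())
        h.update(np.round(self.dirs, 6).tobytes())
        return h.hexdigest()[:16]

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "bvals": self.bvals.tolist(),
            "dirs": self.dirs.tolist(),
            "shell_tol": self.shell_tol,
            "units": "ms/um^2",
            "meta": self.meta,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Protocol":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(np.array(doc["bvals"]), np.array(doc["dirs"]),
                   shell_tol=doc.get("shell_tol", DEFAULT_SHELL_TOL),
                   meta=doc.get("meta", {}))


def read_gradient_table(bval_path: str | Path, bvec_path: str | Path,
                        shell_tol: float = DEFAULT_SHELL_TOL) -> Protocol:
    """Read an FSL-style gradient table (bvals in s/mm^2, bvecs 3 rows).

    b-values are converted to ms/um^2 (divide by 1000) and directions are
    normalized; zero vectors are kept for b=0 volumes.
    """
    try:
        bvals = np.loadtxt(bval_path, dtype=float).ravel()
        bvecs = np.loadtxt(bvec_path, dtype=float)
    except Exception as exc:  # pragma: no cover - loadtxt message passthrough
        raise ProtocolError(f"cannot parse gradient table: {exc}") from exc
    bvecs = np.atleast_2d(bvecs)
    if bvecs.shape[0] != 3:
        raise ProtocolError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != len(bvals):
        raise ProtocolError(
            f"bval/bvec length mismatch: {len(bvals)} vs {bvecs.shape[1]}")
    if np.any(bvals < 0):
        raise ProtocolError("negative b-value in bval file")
    dirs = bvecs.T.copy()
    norms = np.linalg.norm(dirs, axis=1)
    ok = norms > 1e-12
    dirs[ok] /= norms[ok, None]
    return Protocol(bvals / 1000.0, dirs, shell_tol=shell_tol,
                    meta={"source": str(bval_path)})


def default_protocol(n_b0: int = 4, n_b1: int = 20, n_b2: int = 60,
                     b1: float = 1.0, b2: float = 2.0,
                     seed: int | None = 0) -> Protocol:
    """Canonical two-shell clinical protocol: n_b0 x b=0, n_b1 x b=1,
    n_b2 x b=2 ms/um^2 with quasi-uniform (spherical-Fibonacci) directions.

    Deterministic for a given seed; each shell's direction set is rotated by
    an independent random rotation so that the shells do not share axes.
    """
    for name, n in (("n_b1", n_b1), ("n_b2", n_b2)):
        if n < 6:
            raise ProtocolError(f"{name} must be >= 6, got {n}")
    rng = np.random.default_rng(seed)
    d1 = fibonacci_hemisphere(n_b1) @ random_rotation(rng).T
    d2 = fibonacci_hemisphere(n_b2) @ random_rotation(rng).T
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_b1, b1), np.full(n_b2, b2)])
    dirs = np.vstack([np.zeros((n_b0, 3)), d1, d2])
    return Protocol(bvals, dirs, meta={
        "layout": "spherical-fibonacci", "seed": seed,
        "counts": {"b0": n_b0, str(b1): n_b1, str(b2): n_b2}})
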