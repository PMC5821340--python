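"""Gaussian radial-basis-function network core.

The network is the classic three-layer interpolator: hidden unit *i*
responds to an input X with phi_i(X) = exp(-||X - c_i||^2 / (2 sigma^2)),
all units sharing one width

    sigma = d_max / sqrt(2 n),

where d_max is the maximum pairwise distance between the n centers — the
standard heuristic that makes neighbouring Gaussians overlap without
collapsing.  The output is linear in the hidden responses, y = sum w_i
phi_i(X), and the weights solve the linear least-squares problem
Phi w = y in the minimum-norm (pseudo-inverse) sense; a ridge option
exists for ill-conditioned center sets.

Centers live in normalized feature space; the model stores the Normalizer
used at fit time and applies it to raw queries at prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConditioningError, DegenerateCentersError
from .io import Normalizer

#: singular values below RCOND * sigma_max are truncated in the solve
RCOND = 1e-10


def compute_width(centers: np.ndarray) -> float:
    """Shared Gaussian width sigma = d_max / sqrt(2 n) from the center set."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = len(centers)
    if n < 2:
        raise DegenerateCentersError(
            "need at least two centers to derive a width; pass sigma explicitly")
    d_max = cdist(centers, centers).max()
    if d_max == 0:
        raise DegenerateCentersError(
            "all centers coincide (d_max = 0); pass sigma explicitly")
    return float(d_max / np.sqrt(2.0 * n))


def design_matrix(points: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Phi[j, i] = exp(-||x_j - c_i||^2 / (2 sigma^2)); entries in (0, 1]."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sq = cdist(points, centers, "sqeuclidean")
    return np.exp(-sq / (2.0 * sigma ** 2))


def fit_weights(phi: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Solve Phi w = y by minimum-norm least squares (or damped normal eqs)."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    y = np.asarray(y, dtype=float)
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge > 0:
        a = phi.T @ phi + ridge * np.eye(phi.shape[1])
        w = np.linalg.solve(a, phi.T @ y)
    else:
        w, *_ = np.linalg.lstsq(phi, y, rcond=RCOND)
    if not np.isfinite(w).all():
        raise ConditioningError(
            "least-squares solution is not finite; retry with ridge > 0")
    return w


@dataclass
class RBFModel:
    """A fitted Gaussian RBF interpolator over normalized (t, x, y, z)."""

    centers: np.ndarray
    sigma: float
    weights: np.ndarray
    normalizer: Normalizer
    bias: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if len(self.weights) != len(self.centers):
            raise ValueError("one weight per center required")

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def d_max(self) -> float:
        return float(cdist(self.centers, self.centers).max())

    def predict(self, query: np.ndarray) -> np.ndarray:
        """Predict DO (mg/L) at raw (t, x, y, z) queries; vectorized.

        A single 4-vector returns a scalar array of shape (); an (m, 4)
        block returns (m,).
        """
        q = np.asarray(query, dtype=float)
        single = q.ndim == 1
        if not np.isfinite(q).all():
            raise ValueError("query contains non-finite coordinates")
        u = self.normalizer.transform(q)
        phi = design_matrix(u, self.centers, self.sigma)
        out = phi @ self.weights
        if self.bias is not None:
            out = out + self.bias
        return out[0] if single else out

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "oxypond-rbf-model",
            "version": 1,
            "sigma": self.sigma,
            "bias": self.bias,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "normalizer": self.normalizer.to_dict(),
        }

    def save(self, path) -> None:
        """Write a flat JSON model file; serialization is deterministic
        (repr round-trips every float bit-exactly)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RBFModel":
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            sigma=float(d["sigma"]),
            weights=np.asarray(d["weights"], dtype=float),
            normalizer=Normalizer.from_dict(d["normalizer"]),
            bias=None if d.get("bias") is None else float(d["bias"]),
        )

    @classmethod
    def load(cls, path) -> "RBFModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_rbf(
    train_u: np.ndarray,
    y: np.ndarray,
    centers: np.ndarray,
    normalizer: Normalizer,
    sigma: float | None = None,
    ridge: float = 0.0,
    bias: bool = False,
) -> RBFModel:
    """Assemble an RBFModel from normalized training points and centers."""
    if sigma is None:
        sigma = compute_width(centers)
    phi = design_matrix(train_u, centers, sigma)
    if bias:
        phi = np.hstack([phi, np.ones((len(phi), 1))])
        w = fit_weights(phi, y, ridge)
        return RBFModel(centers=centers, sigma=sigma, weights=w[:-1],
                        normalizer=normalizer, bias=float(w[-1]))
    w = fit_weights(phi, y, ridge)
    return RBFModel(centers=centers, sigma=sigma, weights=w, normalizer=normalizer)
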