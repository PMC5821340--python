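"""Deterministic Lloyd-style K-means used to refine density-selected seeds.

Points are assigned to the nearest center by Euclidean distance (ties to
the lowest center index) and centers move to their members' mean until the
largest center displacement falls below a tolerance.  There is no random
initialization here: the seeds come from subtractive clustering, and the
determinism of the combined pipeline is the point.  An empty cluster keeps
its previous center rather than being re-seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class CenterSet:
    """Cluster centers with per-point labels and member counts."""

    centers: np.ndarray          # (k, d)
    labels: np.ndarray           # (n,) ints in [0, k)
    counts: np.ndarray           # (k,)
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.centers)
        if k < 1:
            raise ValueError("CenterSet needs at least one center")
        if np.isnan(self.centers).any():
            raise ValueError("CenterSet contains NaN centers")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError("labels out of range")
        if self.counts.sum() != len(self.labels):
            raise ValueError("counts do not sum to the number of points")

    @property
    def k(self) -> int:
        return len(self.centers)


def assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Label each point with its nearest center; ties break low."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    d = cdist(points, centers)
    return d.argmin(axis=1)  # argmin returns the first (lowest) index on ties


def update_centers(points: np.ndarray, labels: np.ndarray, k: int,
                   previous: np.ndarray | None = None) -> np.ndarray:
    """Mean of each cluster's members; empty clusters keep their old center."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels, dtype=int)
    centers = np.empty((k, points.shape[1]), dtype=float)
    for j in range(k):
        members = points[labels == j]
        if len(members):
            centers[j] = members.mean(axis=0)
        else:
            if previous is None:
                raise ValueError(f"cluster {j} is empty and no previous center given")
            warnings.warn(f"cluster {j} became empty; keeping its previous center",
                          stacklevel=2)
            centers[j] = previous[j]
    return centers


def within_cluster_sse(points: np.ndarray, centers: np.ndarray,
                       labels: np.ndarray) -> float:
    diffs = np.asarray(points, dtype=float) - np.asarray(centers)[labels]
    return float((diffs ** 2).sum())


def kmeans(
    points: np.ndarray,
    init: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> CenterSet:
    """Lloyd iteration from a fixed seed; deterministic given the init.

    Stops when the maximum center displacement drops below ``tol`` (the
    floating-point reading of "no change in the cluster centers") or after
    ``max_iter`` sweeps, in which case ``converged`` is False.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(init, dtype=float)).copy()
    if len(centers) < 1:
        raise ValueError("init must contain at least one center")
    k = len(centers)

    labels = assign(points, centers)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_centers = update_centers(points, labels, k, previous=centers)
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        labels = assign(points, centers)
        if shift < tol:
            converged = True
            break

    counts = np.bincount(labels, minlength=k)
    return CenterSet(centers=centers, labels=labels, counts=counts,
                     converged=converged, n_iter=it)
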