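"""Subtractive clustering: density-ranked selection of cluster count and seeds.

Every data point is a candidate center.  Its density is a Gaussian-weighted
count of neighbours,

    D_i = sum_j exp(-||X_i - X_j||^2 / (alpha/2)^2),

including the self term, so D_i >= 1 always.  The highest-density point
becomes the first center; its influence is then subtracted with a slightly
wider kernel of radius beta = mu * alpha (mu > 1 keeps subsequent centers
from crowding the first),

    D_i <- D_i - D* exp(-||X_i - X*||^2 / (beta/2)^2),

and the argmax is taken again.  Selection stops the first time the
candidate density falls below ``delta`` times the first selected density;
the triggering candidate is discarded.  The procedure yields both the
number of clusters and their initial positions, which seed the K-means
refinement stage.

All coordinates are expected in normalized feature space; ``alpha`` is in
the same units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import CalibrationError


@dataclass(frozen=True)
class ClusterConfig:
    """Hyperparameters of the density-based seeding stage.

    alpha : neighbourhood radius in normalized-feature units.
    mu    : ratio of the suppression radius to alpha (beta = mu * alpha);
            values > 1 discourage adjacent centers.
    delta : stopping factor; selection ends when a candidate's density
            drops below delta times the first center's density.
    """

    alpha: float = 0.5
    mu: float = 1.5
    delta: float = 0.15

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.mu <= 1:
            raise ValueError(f"mu must be > 1, got {self.mu}")
        if not 0 < self.delta < 1:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")

    @property
    def beta(self) -> float:
        return self.mu * self.alpha


@dataclass
class DensityState:
    """Running state of the selection loop, kept for auditing.

    ``chosen`` records (point index, density at selection) in order;
    selected densities are non-increasing by construction.
    """

    densities: np.ndarray
    chosen: list[tuple[int, float]] = field(default_factory=list)

    @property
    def first_density(self) -> float:
        if not self.chosen:
            raise ValueError("no center selected yet")
        return self.chosen[0][1]

    @property
    def center_indices(self) -> list[int]:
        return [i for i, _ in self.chosen]


def compute_densities(points: np.ndarray, alpha: float) -> np.ndarray:
    """Gaussian-weighted neighbour count for every point (self term included)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sq = cdist(points, points, "sqeuclidean")
    return np.exp(-sq / (alpha / 2.0) ** 2).sum(axis=1)


def revise_densities(
    state: DensityState,
    points: np.ndarray,
    center_index: int,
    beta: float,
) -> DensityState:
    """Subtract the chosen center's influence; revised densities floor at 0.

    The raw update can drive densities negative; flooring keeps the
    stopping ratio D_k*/D_1* meaningful.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not 0 <= center_index < len(points):
        raise IndexError(f"center_index {center_index} out of range")
    d_star = state.densities[center_index]
    sq = ((points - points[center_index]) ** 2).sum(axis=1)
    revised = state.densities - d_star * np.exp(-sq / (beta / 2.0) ** 2)
    return DensityState(densities=np.maximum(revised, 0.0), chosen=list(state.chosen))


def subtractive_cluster(
    points: np.ndarray, config: ClusterConfig
) -> tuple[np.ndarray, DensityState]:
    """Select cluster centers by iterated density argmax with suppression.

    Returns (centers, state): centers are the selected input points in
    selection order; the state carries the full selection log.  At least
    one center is always returned.  Argmax ties break to the lowest row
    index, which makes the procedure deterministic and permutation-
    equivariant up to that documented rule.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = len(points)
    state = DensityState(densities=compute_densities(points, config.alpha))

    first = int(np.argmax(state.densities))  # np.argmax: lowest index on ties
    state.chosen.append((first, float(state.densities[first])))
    d1 = state.densities[first]
    state = revise_densities(state, points, first, config.beta)

    while len(state.chosen) < m:
        k = int(np.argmax(state.densities))
        dk = float(state.densities[k])
        if dk / d1 < config.delta:
            break  # triggering candidate is not kept
        state.chosen.append((k, dk))
        state = revise_densities(state, points, k, config.beta)

    centers = points[state.center_indices].copy()
    return centers, state


def cluster_count(points: np.ndarray, config: ClusterConfig) -> int:
    centers, _ = subtractive_cluster(points, config)
    return len(centers)


def _bisect_for_count(points, a_lo, a_hi, target_k, config, n_bisect):
    """Bisect on [a_lo, a_hi] for an alpha with exactly target_k centers.

    The count is a (locally monotone, stepwise) function of alpha; the
    interval is narrowed toward the target and abandoned (None) if it
    collapses without a hit.
    """
    c_lo = cluster_count(points, ClusterConfig(a_lo, config.mu, config.delta))
    c_hi = cluster_count(points, ClusterConfig(a_hi, config.mu, config.delta))
    increasing = c_hi > c_lo
    for _ in range(n_bisect):
        mid = 0.5 * (a_lo + a_hi)
        c = cluster_count(points, ClusterConfig(mid, config.mu, config.delta))
        if c == target_k:
            return float(mid)
        if (c < target_k) == increasing:
            a_lo = mid
        else:
            a_hi = mid
        if (a_hi - a_lo) / a_hi < 1e-14:
            break
    return None


def calibrate_alpha(
    points: np.ndarray,
    target_k: int,
    config: ClusterConfig | None = None,
    n_scan: int = 200,
    n_bisect: int = 50,
) -> float:
    """Find the largest alpha whose cluster count equals ``target_k``.

    The count is not monotone in alpha, so a log-spaced scan of ``n_scan``
    candidates over (0, 2 * max pairwise distance] locates the largest
    achieving candidate first; bisection against the next-larger scanned
    alpha then refines the boundary.  Raises :class:`CalibrationError`
    listing the achievable counts when no candidate hits the target.
    """
    config = config or ClusterConfig()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_distinct = len(np.unique(points, axis=0))
    if target_k < 1:
        raise ValueError(f"target_k must be >= 1, got {target_k}")
    if target_k > n_distinct:
        raise CalibrationError(
            f"{target_k} clusters unreachable: only {n_distinct} distinct "
            f"points (achievable counts are 1..{n_distinct})")

    d_max = cdist(points, points).max()
    if d_max == 0:  # all points identical: any alpha yields one center
        if target_k == 1:
            return config.alpha
        raise CalibrationError("all points identical; only k=1 is achievable")

    alphas = np.geomspace(1e-3 * d_max, 2.0 * d_max, n_scan)
    counts = np.array(
        [cluster_count(points, ClusterConfig(a, config.mu, config.delta)) for a in alphas]
    )
    hits = np.nonzero(counts == target_k)[0]
    if len(hits) == 0:
        # the scan may step over the target (counts jump by >1); bisect
        # inside bracketing intervals, largest alpha first
        for j in range(n_scan - 2, -1, -1):
            lo_c, hi_c = counts[j], counts[j + 1]
            if min(lo_c, hi_c) < target_k < max(lo_c, hi_c):
                a = _bisect_for_count(points, alphas[j], alphas[j + 1],
                                      target_k, config, n_bisect)
                if a is not None:
                    return a
        achievable = sorted(set(counts.tolist()))
        raise CalibrationError(
            f"no alpha in the scan yields {target_k} clusters; "
            f"achievable counts: {achievable}")

    i = int(hits[-1])
    lo = alphas[i]
    if i == n_scan - 1:
        return float(lo)
    hi = alphas[i + 1]  # count != target_k here
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if cluster_count(points, ClusterConfig(mid, config.mu, config.delta)) == target_k:
            lo = mid
        else:
            hi = mid
    return float(lo)
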