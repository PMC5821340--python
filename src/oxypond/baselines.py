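"""Comparison interpolators: trial-count RBF, inverse distance weighting,
and ordinary kriging with a spherical variogram.

The standard RBF baseline fixes the hidden-unit count k by hand (the
trial-and-error practice the hybrid pipeline replaces), initializes
K-means from k distinct training points drawn at random, keeps the best of
several restarts by within-cluster SSE, and then proceeds exactly like the
hybrid path: shared width d_max/sqrt(2n), least-squares weights.

IDW predicts the inverse-distance-power weighted mean of the sample
values in normalized feature space; it interpolates exactly at sample
locations and is bounded by the sample range.

Ordinary kriging works in raw metres over (x, y, z) — the variogram lag
is stated in metres, so normalized units would be meaningless — with the
sampling window treated as a single time slice.  The empirical
semivariance gamma(h) = mean of (y_i - y_j)^2 / 2 per distance bin is fit
with a spherical model by bounded least squares, and each query solves the
ordinary-kriging system with the unbiasedness constraint (weights sum
to 1).  Duplicate sample locations are averaged to keep the system
nonsingular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .io import SampleSet, fit_normalizer
from .kmeans import assign, kmeans, within_cluster_sse
from .rbf import RBFModel, fit_rbf

# ---------------------------------------------------------------------
# standard RBF (trial hidden-unit count, random K-means init)


def standard_rbf_fit(
    train: SampleSet,
    k: int,
    seed: int,
    n_restarts: int = 10,
    ridge: float = 0.0,
    bias: bool = False,
) -> RBFModel:
    """Fit a k-unit RBF with randomly initialized K-means centers.

    ``n_restarts`` independent draws of k distinct training points seed
    K-means; the restart with the lowest within-cluster SSE wins.  Fully
    reproducible for a fixed seed.
    """
    n = len(train)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    normalizer = fit_normalizer(train)
    u = normalizer.transform(train.X)
    rng = np.random.default_rng(seed)

    best = None
    best_sse = np.inf
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        result = kmeans(u, u[idx])
        sse = within_cluster_sse(u, result.centers, result.labels)
        if sse < best_sse:
            best_sse = sse
            best = result

    sigma = None
    if k == 1:
        # single unit: width from the data spread instead of d_max
        sigma = float(max(np.linalg.norm(u - best.centers[0], axis=1).max(), 1e-12))
    return fit_rbf(u, train.y, best.centers, normalizer, sigma=sigma,
                   ridge=ridge, bias=bias)


# ---------------------------------------------------------------------
# inverse distance weighting


def idw_predict(
    train: SampleSet,
    query: np.ndarray,
    power: float = 2.0,
    normalize: bool = True,
) -> np.ndarray:
    """Inverse-distance-power weighted mean; exact at sample locations."""
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)

    if normalize:
        norm = fit_normalizer(train)
        pts = norm.transform(train.X)
        qs = norm.transform(q)
    else:
        pts, qs = train.X, q
    y = train.y

    d = cdist(qs, pts)
    out = np.empty(len(qs))
    for i in range(len(qs)):
        hit = d[i] == 0
        if hit.any():
            out[i] = y[hit][0]  # coincident sample: return its value exactly
            continue
        w = d[i] ** (-power)
        out[i] = (w * y).sum() / w.sum()
    return out[0] if single else out


# ---------------------------------------------------------------------
# ordinary kriging, spherical variogram


@dataclass
class VariogramModel:
    """Spherical variogram: nugget + sill rise to a plateau at ``range_``."""

    nugget: float
    sill: float        # total sill (nugget + partial sill)
    range_: float
    lag: float = 100.0
    n_lags: int = 20
    model: str = "spherical"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ValueError(
                f"invalid variogram: nugget={self.nugget}, sill={self.sill}, "
                f"range={self.range_}")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c = self.sill - self.nugget
        ratio = np.clip(h / self.range_, 0.0, 1.0)
        gamma = self.nugget + c * (1.5 * ratio - 0.5 * ratio ** 3)
        return np.where(h == 0, 0.0, gamma)


def empirical_variogram(
    coords: np.ndarray, values: np.ndarray, lag: float, n_lags: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned semivariances: returns (bin centers, gamma, pair counts)."""
    if lag <= 0:
        raise ValueError("lag must be > 0")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.asarray(values, dtype=float)
    d = cdist(coords, coords)
    iu = np.triu_indices(len(coords), k=1)
    dist = d[iu]
    semi = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2

    edges = np.arange(0.0, lag * n_lags + lag, lag)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (dist > lo) & (dist <= hi)
        if m.any():
            centers.append(0.5 * (lo + hi))
            gammas.append(semi[m].mean())
            counts.append(int(m.sum()))
    return np.asarray(centers), np.asarray(gammas), np.asarray(counts)


def fit_variogram(
    train: SampleSet, lag: float = 100.0, n_lags: int = 20
) -> VariogramModel:
    """Fit a spherical model to the empirical variogram by least squares.

    Distances are raw metres over (x, y, z); time is ignored (one survey
    window).  Bins are weighted by pair count.
    """
    if len(train) < 3:
        raise ValueError("need at least 3 samples to fit a variogram")
    coords = train.X[:, 1:4]
    h, gamma, counts = empirical_variogram(coords, train.y, lag, n_lags)
    if len(h) < 2:
        # all pairs in one bin: flat pure-nugget fallback
        g = float(gamma[0]) if len(gamma) else float(np.var(train.y))
        g = max(g, 1e-12)
        return VariogramModel(nugget=0.0, sill=g, range_=max(h.max(), lag),
                              lag=lag, n_lags=n_lags)

    w = np.sqrt(counts)
    g_max = max(gamma.max(), 1e-12)
    h_max = h.max()

    def resid(p):
        nugget, psill, rng = p
        model = VariogramModel(nugget=nugget, sill=nugget + psill,
                               range_=rng, lag=lag, n_lags=n_lags)
        return w * (model(h) - gamma)

    x0 = np.array([0.0, g_max, 0.5 * h_max])
    sol = least_squares(
        resid, x0,
        bounds=([0.0, 1e-12, 1e-6], [g_max, 10 * g_max, 10 * h_max]),
    )
    nugget, psill, rng = sol.x
    return VariogramModel(nugget=float(nugget), sill=float(nugget + psill),
                          range_=float(rng), lag=lag, n_lags=n_lags)


def _dedupe(coords: np.ndarray, values: np.ndarray):
    """Average values at duplicate coordinates (singular-system guard)."""
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    warnings.warn("duplicate sample locations averaged for kriging", stacklevel=3)
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, values)
    np.add.at(counts, inverse, 1.0)
    return uniq, sums / counts


def kriging_predict(
    train: SampleSet,
    vgm: VariogramModel,
    query: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging prediction and variance at (x, y, z) queries.

    Queries may be given as raw (t, x, y, z) 4-vectors (time dropped) or
    bare (x, y, z) 3-vectors.  Returns (values, kriging variances).
    """
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] == 4:
        q = q[:, 1:4]
    coords, values = _dedupe(train.X[:, 1:4], train.y)
    n = len(coords)

    # ordinary-kriging system in gamma form with Lagrange multiplier
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = vgm(cdist(coords, coords))
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0

    b = np.empty((n + 1, len(q)))
    b[:n] = vgm(cdist(coords, q))
    b[n] = 1.0

    sol = np.linalg.solve(a, b)
    weights = sol[:n]
    lagrange = sol[n]
    preds = weights.T @ values
    variances = (weights * b[:n]).sum(axis=0) + lagrange
    variances = np.maximum(variances, 0.0)
    if single:
        return preds[0], variances[0]
    return preds, variances


def kriging_weights(
    train: SampleSet, vgm: VariogramModel, query: np.ndarray
) -> np.ndarray:
    """Kriging weights at one query (they sum to 1 by construction)."""
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] == 4:
        q = q[:, 1:4]
    coords, values = _dedupe(train.X[:, 1:4], train.y)
    n = len(coords)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = vgm(cdist(coords, coords))
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    b = np.concatenate([vgm(cdist(coords, q)).ravel(), [1.0]])
    return np.linalg.solve(a, b)[:n]
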