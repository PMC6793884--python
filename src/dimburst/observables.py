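"""Measured quantities: complexity counts, evolutionary speed, clustering.

The central bookkeeping notion is the *phenotypic dimension* of a cluster
or individual: the first coordinate is always possessed, and a costly
coordinate ``x_k`` (k >= 2) counts as acquired once it exceeds twice the
birth-penalty width, ``x_k > 2 sigma_beta`` — beyond that point the
birth-rate cost is essentially paid in full and the trait behaves as an
established capability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter, maximum_filter

from .equilibrium import Community
from .model import ModelParams, selection_gradients

__all__ = [
    "phenotype_dimension",
    "DimensionCounts",
    "counts_by_dimension",
    "average_dimension",
    "evolutionary_speed",
    "detect_clusters_points",
    "detect_clusters_density",
    "expansion_times",
]


def phenotype_dimension(x, sigma_beta: float) -> int:
    """Number of acquired phenotypic dimensions of a single phenotype.

    Returns ``1 + #{i >= 2 : x_i > 2 sigma_beta}``; the first coordinate is
    always counted regardless of its value, and acquired coordinates count
    in any order.
    """
    arr = np.asarray(x, dtype=float)
    return 1 + int(np.sum(arr[1:] > 2.0 * sigma_beta))


def _dimensions(X: np.ndarray, sigma_beta: float) -> np.ndarray:
    """Vectorized phenotype dimension for rows of an (n, d) matrix."""
    if X.size == 0:
        return np.zeros(0, dtype=int)
    return 1 + np.sum(X[:, 1:] > 2.0 * sigma_beta, axis=1)


@dataclass
class DimensionCounts:
    """Per-dimension counts over time, raw and time-window smoothed."""

    times: np.ndarray          # (T,)
    counts: np.ndarray         # (T, d_max) integer counts
    smoothed: np.ndarray       # (T, d_max) centred running average
    window: float              # width of the averaging window (time units)


def _phenotype_stack(snapshot) -> np.ndarray:
    """Accept a Community or a bare (n, d) array of phenotypes."""
    if isinstance(snapshot, Community):
        return snapshot.phenotype_matrix()
    return np.atleast_2d(np.asarray(snapshot, dtype=float))


def counts_by_dimension(
    snapshots, sigma_beta: float, d_max: int, window: float = 10.0
) -> DimensionCounts:
    """Histogram of phenotype dimensions per snapshot, with running average.

    Parameters
    ----------
    snapshots : sequence of (time, Community-or-array) pairs, time-ordered.
        For adaptive dynamics the entries are clusters; for the
        individual-based model they are individuals.
    sigma_beta, d_max : model constants used for the dimension rule.
    window : width (in time units) of the centred moving average.
    """
    times = np.array([t for t, _ in snapshots], dtype=float)
    T = len(times)
    counts = np.zeros((T, d_max), dtype=int)
    for k, (_, snap) in enumerate(snapshots):
        X = _phenotype_stack(snap)
        if X.size == 0:
            continue
        dims = _dimensions(X, sigma_beta)
        counts[k] = np.bincount(dims, minlength=d_max + 1)[1 : d_max + 1]
    smoothed = np.empty_like(counts, dtype=float)
    half = window / 2.0
    for k, t in enumerate(times):
        sel = (times >= t - half) & (times <= t + half)
        smoothed[k] = counts[sel].mean(axis=0)
    return DimensionCounts(times, counts, smoothed, window)


def average_dimension(community) -> float:
    """Unweighted mean phenotype dimension over clusters (in [1, d_max])."""
    if isinstance(community, Community):
        sigma_beta = community.params.sigma_beta
        X = community.phenotype_matrix()
    else:  # (X, sigma_beta) pair for bare arrays
        X, sigma_beta = community
        X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("average dimension of an empty community is undefined")
    return float(np.mean(_dimensions(X, sigma_beta)))


def evolutionary_speed(community: Community, p: ModelParams) -> float:
    """Population-weighted mean norm of the selection gradient.

    Returns ``sum_r (N_r / sum N) * ||s(x_r)||``; zero for an empty
    community.  This is the instantaneous speed of phenotypic change per
    unit population, the quantity whose intermittent bursts accompany
    expansions into new dimensions.
    """
    if len(community) == 0:
        return 0.0
    X = community.phenotype_matrix()
    N = community.populations()
    S = selection_gradients(X, N, p)
    norms = np.linalg.norm(S, axis=1)
    tot = N.sum()
    if tot <= 0:
        return float(norms.mean())
    return float(np.sum(N / tot * norms))


def detect_clusters_points(
    points, link_threshold: float = 0.15, min_frac: float = 0.01
) -> list[tuple[np.ndarray, int]]:
    """Group a point cloud into clusters by single-linkage at a threshold.

    Connected components of the graph linking points closer than
    ``link_threshold`` become clusters; components holding fewer than
    ``min_frac`` of all points are discarded as transients.

    Returns a list of ``(centroid, size)`` pairs, largest first.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.size == 0:
        return []
    n = X.shape[0]
    if n == 1:
        return [(X[0].copy(), 1)]
    Z = linkage(X, method="single")
    labels = fcluster(Z, t=link_threshold, criterion="distance")
    out = []
    for lab in np.unique(labels):
        members = X[labels == lab]
        if len(members) < max(1, min_frac * n):
            continue
        out.append((members.mean(axis=0), len(members)))
    out.sort(key=lambda cs: -cs[1])
    return out


def detect_clusters_density(
    field, smooth_width: float = 1.5, rel_threshold: float = 0.1
) -> list[np.ndarray]:
    """Peak locations of a gridded density field.

    The field is Gaussian-smoothed (``smooth_width`` in grid cells) and
    local maxima above ``rel_threshold`` times the global maximum are
    reported.  Accepts a DensityField (with ``phi`` and ``coords``) or a
    bare 2-D array (peaks then in index units).
    """
    phi = getattr(field, "phi", field)
    phi = np.asarray(phi, dtype=float)
    if phi.max() <= 0:
        return []
    sm = gaussian_filter(phi, smooth_width, mode="nearest")
    localmax = sm == maximum_filter(sm, size=5, mode="nearest")
    peaks = np.argwhere(localmax & (sm > rel_threshold * sm.max()))
    coords = getattr(field, "coords", None)
    if coords is None:
        return [idx.astype(float) for idx in peaks]
    xs, ys = coords
    return [np.array([xs[i], ys[j]]) for i, j in peaks]


def expansion_times(counts: DimensionCounts) -> dict[int, float]:
    """First time each dimension ``k >= 2`` is acquired by any cluster.

    Returns a map ``{k: time}`` from the raw (unsmoothed) counts; a
    dimension never acquired is absent.
    """
    out: dict[int, float] = {}
    for k in range(2, counts.counts.shape[1] + 1):
        hit = np.nonzero(counts.counts[:, k - 1] > 0)[0]
        if hit.size:
            out[k] = float(counts.times[hit[0]])
    return out
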