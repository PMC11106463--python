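"""Empirical semivariogram of a regional variable and range detection.

The Matheron estimator is used: for pairs whose separation falls in a lag
bin, gamma(h) = (1 / 2N(h)) * sum (z_i - z_j)^2. Under positive spatial
autocorrelation gamma rises with distance and plateaus near the sample
variance (the sill); the distance of plateau onset (the range) sets the
spatial-blocking scale for cross-validation.

The plateau is detected automatically as the first (smoothed) bin reaching
a fraction of the sill, replacing the discretionary visual judgement common
in practice; callers can always override the range explicitly.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .types import Semivariogram

EARTH_RADIUS_KM = 6371.0


def pairwise_distances(centroids: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric distance matrix between points.

    metric="euclidean" treats coordinates as planar; metric="haversine"
    expects (lon, lat) in degrees and returns great-circle km on a sphere of
    radius 6371 km.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise InvalidInputError("need >= 2 points of shape (n, 2)")
    if metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(pts))
    if metric == "haversine":
        lat = pts[:, 1]
        if np.any(np.abs(lat) > 90):
            raise InvalidInputError("latitude outside [-90, 90] degrees")
        from sklearn.metrics.pairwise import haversine_distances

        rad = np.radians(pts[:, [1, 0]])  # haversine wants (lat, lon) radians
        return haversine_distances(rad) * EARTH_RADIUS_KM
    raise InvalidInputError(f"unknown metric {metric!r}")


def default_bin_edges(distmat: np.ndarray, n_bins: int = 15) -> np.ndarray:
    """Equal-width lag bins from 0 to half the maximum pairwise distance."""
    return np.linspace(0.0, float(np.max(distmat)) / 2.0, n_bins + 1)


def empirical_semivariogram(
    values: np.ndarray, distmat: np.ndarray, bin_edges: np.ndarray
) -> Semivariogram:
    """Binned Matheron semivariance over all unordered point pairs.

    Empty bins carry gamma = NaN and pair_count 0. The stored sill estimate
    is the sample variance (ddof=1) of the input values.
    """
    values = np.asarray(values, dtype=float)
    distmat = np.asarray(distmat, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0) or bin_edges[0] < 0:
        raise InvalidInputError("bin_edges must be strictly increasing and start >= 0")
    n = len(values)
    iu, ju = np.triu_indices(n, k=1)
    d = distmat[iu, ju]
    sq = (values[iu] - values[ju]) ** 2

    # right-inclusive last edge so the half-max-distance bin keeps its pairs
    idx = np.digitize(d, bin_edges) - 1
    idx[d == bin_edges[-1]] = len(bin_edges) - 2
    n_bins = len(bin_edges) - 1
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            gamma[b] = sq[mask].sum() / (2.0 * counts[b])
    if counts.sum() == 0:
        raise InvalidInputError("all lag bins are empty")
    return Semivariogram(
        bin_edges=bin_edges,
        bin_centers=0.5 * (bin_edges[:-1] + bin_edges[1:]),
        gamma=gamma,
        pair_counts=counts,
        sill_estimate=float(np.var(values, ddof=1)),
    )


def estimate_range(
    sv: Semivariogram, threshold: float = 0.95, smooth_window: int = 3
) -> Semivariogram:
    """Detect the plateau onset: first bin with gamma >= threshold * sill.

    gamma is moving-average smoothed over non-empty bins (centered window)
    before scanning. If the threshold is never reached the last non-empty
    bin center is returned with ``converged=False``. Returns the
    semivariogram with range_estimate and converged filled in.
    """
    nonempty = sv.pair_counts > 0
    if nonempty.sum() < 3:
        raise InvalidInputError("need >= 3 non-empty bins to estimate a range")
    centers = sv.bin_centers[nonempty]
    g = sv.gamma[nonempty]
    if smooth_window > 1:
        half = smooth_window // 2
        sm = np.array(
            [g[max(0, i - half): i + half + 1].mean() for i in range(len(g))]
        )
    else:
        sm = g
    crossing = np.nonzero(sm >= threshold * sv.sill_estimate)[0]
    if len(crossing):
        sv.range_estimate = float(centers[crossing[0]])
        sv.converged = True
    else:
        sv.range_estimate = float(centers[-1])
        sv.converged = False
    return sv
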