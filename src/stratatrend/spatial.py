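"""Areal neighbourhood structure and CAR precision matrices.

Survey strata are treated as areal units represented by their centroids
(in decimal degrees).  Two strata are neighbours when the plain Euclidean
distance between their centroids is at or below a threshold distance; the
resulting binary proximity matrix ``W`` and its row-sum diagonal ``D``
define the proper conditional autoregressive (CAR) precision

    Q = tau * (D - lam * W),   tau > 0,  0 <= lam < 1,

which is the joint precision of one time-slice of the spatial random
field.  ``Q`` is strictly diagonally dominant (hence positive definite)
whenever every stratum has at least one neighbour and ``lam < 1``.

Distances are deliberately *not* geodesic: the survey design works in raw
decimal degrees, and the neighbour rule is defined on those coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StrataGraph",
    "build_proximity_matrix",
    "min_connecting_threshold",
    "car_precision",
    "car_logdet",
    "sample_car",
    "greedy_coloring",
    "read_centroids",
    "write_centroids",
]


class DisconnectedGraphError(ValueError):
    """Raised when a caller demands a fully connected neighbourhood."""


@dataclass(frozen=True)
class StrataGraph:
    """Neighbourhood structure of the survey strata.

    Attributes
    ----------
    stratum_ids : tuple of str
        Ordered stratum identifiers; the row/column order of ``W``.
    centroids : ndarray, shape (m, 2)
        Centroid coordinates in decimal degrees.
    threshold : float
        Neighbour distance: strata with centroid distance <= threshold
        are neighbours (ties count as neighbours).
    W : ndarray, shape (m, m)
        Symmetric binary proximity matrix, zero diagonal.
    D : ndarray, shape (m, m)
        Diagonal matrix of the row sums of ``W``.
    isolated : tuple of str
        Strata with no neighbour at this threshold (warning flag; fatal
        only if the caller demands connectivity).
    """

    stratum_ids: tuple
    centroids: np.ndarray
    threshold: float
    W: np.ndarray
    D: np.ndarray
    isolated: tuple = field(default=())

    @property
    def m(self) -> int:
        return len(self.stratum_ids)

    @property
    def is_connected_enough(self) -> bool:
        """True when every stratum has at least one neighbour."""
        return len(self.isolated) == 0

    def require_connected(self) -> "StrataGraph":
        if self.isolated:
            raise DisconnectedGraphError(
                f"strata without neighbours at threshold {self.threshold}: "
                f"{list(self.isolated)}; use min_connecting_threshold() to "
                "find the smallest distance at which all strata connect"
            )
        return self

    def index_of(self, stratum) -> int:
        return self.stratum_ids.index(stratum)

    def to_frames(self):
        """W and D as labelled DataFrames for inspection/export."""
        ids = list(self.stratum_ids)
        return (
            pd.DataFrame(self.W.astype(int), index=ids, columns=ids),
            pd.DataFrame(self.D.astype(int), index=ids, columns=ids),
        )

    def write(self, w_path, d_path=None) -> None:
        w, d = self.to_frames()
        w.to_csv(w_path)
        if d_path is not None:
            d.to_csv(d_path)


def _as_centroids(centroids) -> np.ndarray:
    arr = np.asarray(centroids, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"centroids must be (m, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("centroids must be finite")
    return arr


def _pairwise_distances(arr: np.ndarray) -> np.ndarray:
    diff = arr[:, None, :] - arr[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def build_proximity_matrix(centroids, threshold, stratum_ids=None) -> StrataGraph:
    """Build the binary proximity matrix from centroid coordinates.

    Parameters
    ----------
    centroids : array-like, shape (m, 2)
        Stratum centroid coordinates in decimal degrees.
    threshold : float
        Neighbour distance; pairs at distance <= threshold (Euclidean on
        the raw coordinates) are neighbours.
    stratum_ids : sequence of str, optional
        Identifiers; defaults to "s1".."sm".  Duplicates are rejected.

    Returns
    -------
    StrataGraph
        With ``isolated`` listing any stratum that has no neighbour.
    """
    arr = _as_centroids(centroids)
    m = arr.shape[0]
    if m < 2:
        raise ValueError("need at least 2 strata")
    threshold = float(threshold)
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if stratum_ids is None:
        stratum_ids = tuple(f"s{i + 1}" for i in range(m))
    else:
        stratum_ids = tuple(str(s) for s in stratum_ids)
        if len(stratum_ids) != m:
            raise ValueError("stratum_ids length does not match centroids")
        if len(set(stratum_ids)) != m:
            raise ValueError("duplicate stratum ids")

    dist = _pairwise_distances(arr)
    if np.any(dist[np.triu_indices(m, k=1)] == 0.0):
        warnings.warn("coincident centroids found (distance 0); they are "
                      "treated as neighbours", stacklevel=2)

    W = ((dist <= threshold) & ~np.eye(m, dtype=bool)).astype(float)
    D = np.diag(W.sum(axis=1))
    isolated = tuple(sid for sid, d in zip(stratum_ids, np.diag(D)) if d == 0)
    if isolated:
        warnings.warn(f"strata with no neighbours at threshold {threshold}: "
                      f"{list(isolated)}", stacklevel=2)
    return StrataGraph(stratum_ids=stratum_ids, centroids=arr,
                       threshold=threshold, W=W, D=D, isolated=isolated)


def min_connecting_threshold(centroids) -> float:
    """Shortest distance at which every stratum has at least one neighbour.

    Equals the maximum over strata of the distance to the nearest other
    stratum; by construction a graph built at exactly this threshold has
    every row sum of W >= 1 (ties count as neighbours).
    """
    arr = _as_centroids(centroids)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 strata")
    dist = _pairwise_distances(arr)
    np.fill_diagonal(dist, np.inf)
    return float(dist.min(axis=1).max())


def car_precision(graph: StrataGraph, tau: float, lam: float) -> np.ndarray:
    """Proper-CAR precision Q = tau * (D - lam * W).

    Positive definite whenever the graph has no isolated stratum and
    ``0 <= lam < 1`` (strict diagonal dominance).  ``lam = 0`` gives
    independent effects with variance 1/(tau * d_j).
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if not (0.0 <= lam < 1.0):
        raise ValueError("lam must lie in [0, 1)")
    if graph.isolated:
        raise DisconnectedGraphError(
            f"CAR precision is singular: stratum/strata {list(graph.isolated)} "
            "have no neighbours (zero row sum in D)"
        )
    Q = tau * (graph.D - lam * graph.W)
    # Enforce exact symmetry (D diagonal, W symmetric, so this is a no-op
    # up to the arithmetic already performed).
    return (Q + Q.T) / 2.0


def car_logdet(graph: StrataGraph, tau: float, lam: float,
               _eigs_cache: dict = {}) -> float:
    """log det of the CAR precision via the normalized adjacency spectrum.

    det(tau(D - lam W)) = tau^m * det(D) * prod_i (1 - lam * v_i) where
    v_i are the eigenvalues of D^{-1/2} W D^{-1/2}.
    """
    graph.require_connected()
    key = id(graph)
    if key not in _eigs_cache:
        d = np.diag(graph.D)
        s = 1.0 / np.sqrt(d)
        Wn = graph.W * s[:, None] * s[None, :]
        _eigs_cache.clear()  # keep a single-graph cache
        _eigs_cache[key] = (np.linalg.eigvalsh(Wn), np.log(d).sum())
    eigs, logdetD = _eigs_cache[key]
    m = graph.m
    return float(m * np.log(tau) + logdetD + np.log1p(-lam * eigs).sum())


def sample_car(graph: StrataGraph, tau: float, lam: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` fields x ~ Normal(0, Q^{-1}) with Q = tau(D - lam W).

    Uses the upper Cholesky factor: if Q = L L', then x = L'^{-1} z with
    z ~ N(0, I) has covariance Q^{-1}.  Returns shape (size, m).
    """
    Q = car_precision(graph, tau, lam)
    L = np.linalg.cholesky(Q)
    z = rng.standard_normal((size, graph.m))
    from scipy.linalg import solve_triangular

    return solve_triangular(L.T, z.T, lower=False).T


def greedy_coloring(W: np.ndarray) -> np.ndarray:
    """Greedy vertex colouring of the neighbour graph (largest degree first).

    Vertices sharing a colour are mutually non-adjacent, so their CAR full
    conditionals are independent given the rest — used for vectorised
    single-site updates.
    """
    m = W.shape[0]
    order = np.argsort(-W.sum(axis=1), kind="stable")
    colors = np.full(m, -1, dtype=int)
    for v in order:
        used = {colors[u] for u in np.nonzero(W[v])[0] if colors[u] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[v] = c
    return colors


def read_centroids(path):
    """Read a centroid file (CSV with header ``stratum,x,y``).

    Returns (stratum_ids, centroids) ready for build_proximity_matrix.
    """
    df = pd.read_csv(path, dtype={"stratum": str})
    missing = {"stratum", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid file missing columns: {sorted(missing)}")
    return tuple(df["stratum"]), df[["x", "y"]].to_numpy(dtype=float)


def write_centroids(path, stratum_ids, centroids) -> None:
    arr = _as_centroids(centroids)
    pd.DataFrame({"stratum": list(stratum_ids),
                  "x": arr[:, 0], "y": arr[:, 1]}).to_csv(path, index=False)
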