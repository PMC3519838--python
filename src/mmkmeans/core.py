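"""Distances, objective, initialization, and the Lloyd (Traditional) loop.

All k-means variants in this package share these primitives.  The objective
reported in traces is always the mean squared Euclidean distance of each
point to its assigned centroid (MSE), regardless of the distance kind used
for assignment, so that convergence curves are comparable across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .io import DataMatrix, PartitionLabels

logger = logging.getLogger(__name__)

DISTANCE_KINDS = ("sq_euclidean", "euclidean", "pearson_dissimilarity")
INIT_METHODS = ("forgy_sample", "first_k")


@dataclass
class AlgoConfig:
    """Tunables shared by every k-means variant.

    The stability-band constants come from the empirical observation that
    the spectral lower bound on the optimal k-means objective sits within
    0.5%--1.5% of the optimum: ``L0`` = 0.005 and ``H1`` = 0.015 bound the
    relative eigenvalue change below which a cluster is declared stable.
    ``epsilon`` = 0.007 is the convergence band half-width used to detect
    the iteration at which the stability mechanism switches on; in
    ``relative`` mode (default) it is scaled by the first-iteration MSE so
    the criterion is scale-free, in ``absolute`` mode it is used as-is
    (appropriate for normalized expression data of magnitude ~1).
    """

    k: int
    seed: int = 0
    max_iter: int = 300
    distance: str = "sq_euclidean"
    init: str = "forgy_sample"
    L0: float = 0.005
    H1: float = 0.015
    epsilon: float = 0.007
    epsilon_mode: str = "relative"
    stability_mode: str = "threshold"
    mmi_override: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 <= self.L0 < self.H1):
            raise ValueError("need 0 <= L0 < H1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.distance not in DISTANCE_KINDS:
            raise ValueError(f"distance must be one of {DISTANCE_KINDS}")
        if self.init not in INIT_METHODS:
            raise ValueError(f"init must be one of {INIT_METHODS}")
        if self.epsilon_mode not in ("relative", "absolute"):
            raise ValueError("epsilon_mode must be 'relative' or 'absolute'")
        if self.stability_mode not in ("threshold", "strict_interval"):
            raise ValueError("stability_mode must be 'threshold' or 'strict_interval'")
        if self.mmi_override is not None and self.mmi_override < 1:
            raise ValueError("mmi_override must be >= 1")


@dataclass
class CentroidSet:
    """k mean vectors with per-cluster member counts.

    A cluster that loses all members keeps its previous mean and reports
    size 0 (empty clusters are not re-seeded).
    """

    means: np.ndarray  # k x d
    sizes: np.ndarray  # k

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.means.ndim != 2 or self.sizes.shape != (self.means.shape[0],):
            raise ValueError("means must be k x d with one size per cluster")

    @property
    def k(self) -> int:
        return self.means.shape[0]


@dataclass
class ClusteringState:
    """Full state of one iteration: centroids, labels, freeze flags."""

    centroids: CentroidSet
    labels: Optional[np.ndarray]
    prev_centroids: Optional[CentroidSet]
    frozen: np.ndarray  # k booleans; all False for non-MM variants
    iteration: int  # 1-based


@dataclass
class IterationRecord:
    iteration: int
    mse: float
    moved: int
    stable_clusters: int
    dist_evals: int  # cumulative over the run


@dataclass
class RunTrace:
    """Per-iteration MSE, moved-point count, frozen-cluster count, and the
    cumulative number of point-centroid distance evaluations."""

    records: list[IterationRecord] = field(default_factory=list)

    def append(self, iteration: int, mse: float, moved: int,
               stable_clusters: int, dist_evals: int) -> None:
        self.records.append(
            IterationRecord(iteration, float(mse), int(moved),
                            int(stable_clusters), int(dist_evals))
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mse_values(self) -> np.ndarray:
        return np.array([r.mse for r in self.records])

    @property
    def total_dist_evals(self) -> int:
        return self.records[-1].dist_evals if self.records else 0

    def per_iteration_dist_evals(self) -> np.ndarray:
        cum = np.array([r.dist_evals for r in self.records])
        return np.diff(cum, prepend=0)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation between two vectors of length >= 2.

    A zero-variance vector has no defined correlation; by convention the
    function returns 0.0 and logs a warning, so that downstream correlation
    matrices stay finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("pearson_r requires length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        logger.warning("pearson_r: zero-variance vector, returning 0")
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def distance(x: np.ndarray, y: np.ndarray, kind: str = "sq_euclidean") -> float:
    """Distance between two d-vectors.

    ``sq_euclidean``: sum of squared coordinate differences;
    ``euclidean``: its square root;
    ``pearson_dissimilarity``: 1 - r(x, y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dimension mismatch")
    if kind == "sq_euclidean":
        diff = x - y
        return float(diff @ diff)
    if kind == "euclidean":
        diff = x - y
        return float(np.sqrt(diff @ diff))
    if kind == "pearson_dissimilarity":
        return 1.0 - pearson_r(x, y)
    raise ValueError(f"unknown distance kind {kind!r}")


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm; zero-variance rows become 0."""
    C = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        logger.warning("zero-variance rows in correlation computation -> r = 0")
    norms[zero] = 1.0
    C = C / norms
    C[zero] = 0.0
    return C


def distance_matrix(X: np.ndarray, means: np.ndarray, kind: str) -> np.ndarray:
    """All point-to-centroid distances, rows = points, columns = centroids."""
    if kind == "sq_euclidean":
        return cdist(X, means, metric="sqeuclidean")
    if kind == "euclidean":
        return cdist(X, means, metric="euclidean")
    if kind == "pearson_dissimilarity":
        return 1.0 - _standardize_rows(X) @ _standardize_rows(means).T
    raise ValueError(f"unknown distance kind {kind!r}")


def point_to_assigned(X: np.ndarray, means: np.ndarray, labels: np.ndarray,
                      kind: str) -> np.ndarray:
    """Distance of each point to the centroid it is currently assigned to."""
    diffs = X - means[labels]
    if kind == "sq_euclidean":
        return np.einsum("ij,ij->i", diffs, diffs)
    if kind == "euclidean":
        return np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    if kind == "pearson_dissimilarity":
        sx = _standardize_rows(X)
        sm = _standardize_rows(means)
        return 1.0 - np.einsum("ij,ij->i", sx, sm[labels])
    raise ValueError(f"unknown distance kind {kind!r}")


def mse(data: DataMatrix, centroids: CentroidSet, labels: np.ndarray) -> float:
    """Mean squared Euclidean distance of each point to its centroid.

    Always squared-Euclidean, independent of the assignment distance kind,
    so objective curves are comparable across runs.
    """
    diffs = data.values - centroids.means[labels]
    return float(np.einsum("ij,ij->i", diffs, diffs).mean())


def init_centroids(data: DataMatrix, config: AlgoConfig) -> CentroidSet:
    """Choose k initial centroids from the data rows.

    ``forgy_sample`` draws k distinct rows without replacement using
    ``config.seed``; ``first_k`` takes rows 0..k-1.  Both are deterministic
    given the config, which is what makes shared-initialization comparisons
    across algorithm variants meaningful.
    """
    if data.n < config.k:
        raise ValueError(f"n={data.n} < k={config.k}")
    if config.init == "first_k":
        idx = np.arange(config.k)
    else:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(data.n, size=config.k, replace=False)
    return CentroidSet(means=data.values[idx].copy(),
                       sizes=np.zeros(config.k, dtype=int))


def assign_points(
    data: DataMatrix,
    centroids: CentroidSet,
    frozen: Optional[np.ndarray],
    prev_labels: Optional[np.ndarray],
    distance_kind: str = "sq_euclidean",
) -> tuple[np.ndarray, int, int]:
    """Assign each point to its nearest centroid, honoring frozen clusters.

    A point whose previous cluster is frozen keeps its label and costs no
    distance evaluations.  Every other point is compared against all k
    centroids (frozen ones included — a frozen cluster may still gain
    points).  Nearest-centroid ties resolve to the lowest cluster index.

    Returns ``(labels, moved_count, dist_evals)`` where ``dist_evals`` is
    the number of point-centroid distance computations performed.
    """
    X = data.values
    n = X.shape[0]
    k = centroids.k

    if frozen is not None and prev_labels is not None and frozen.any():
        active = ~frozen[prev_labels]
    else:
        active = np.ones(n, dtype=bool)

    labels = np.empty(n, dtype=int)
    if prev_labels is not None:
        labels[:] = prev_labels
    n_active = int(active.sum())
    if n_active:
        D = distance_matrix(X[active], centroids.means, distance_kind)
        labels[active] = D.argmin(axis=1)  # argmin takes the lowest index on ties
    dist_evals = n_active * k
    if prev_labels is None:
        moved = n
    else:
        moved = int((labels != prev_labels).sum())
    return labels, moved, dist_evals


def update_centroids(data: DataMatrix, labels: np.ndarray, k: int,
                     previous: CentroidSet) -> CentroidSet:
    """Recompute cluster means; an empty cluster keeps its previous mean."""
    X = data.values
    sizes = np.bincount(labels, minlength=k)
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, labels, X)
    means = previous.means.copy()
    nonempty = sizes > 0
    means[nonempty] = sums[nonempty] / sizes[nonempty, None]
    return CentroidSet(means=means, sizes=sizes)


def run_traditional(
    data: DataMatrix, config: AlgoConfig
) -> tuple[PartitionLabels, CentroidSet, RunTrace]:
    """Lloyd's algorithm: alternate assignment and mean update.

    Iterates until no point changes cluster or ``max_iter`` is reached.
    The trace records MSE after each assignment step (so MSE of iteration 1
    is the objective under the initial centroids), and with squared
    Euclidean assignment the recorded MSE sequence is non-increasing.
    """
    centroids = init_centroids(data, config)
    trace = RunTrace()
    labels: Optional[np.ndarray] = None
    cum_evals = 0
    for i in range(1, config.max_iter + 1):
        new_labels, moved, evals = assign_points(
            data, centroids, None, labels, config.distance
        )
        cum_evals += evals
        trace.append(i, mse(data, centroids, new_labels), moved, 0, cum_evals)
        labels = new_labels
        if moved == 0:
            break
        centroids = update_centroids(data, labels, config.k, centroids)
    assert labels is not None
    centroids = update_centroids(data, labels, config.k, centroids)
    return PartitionLabels(ids=list(data.ids), labels=labels), centroids, trace
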