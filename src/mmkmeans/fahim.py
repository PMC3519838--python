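"""Overlapped and Enhanced k-means with per-point reassignment shortcuts.

Both variants keep two per-point arrays — ``clusterid`` (assigned cluster)
and ``pointdis`` (a stored distance to a centroid of that cluster).  After
each centroid update, a point whose distance to its cluster's *new*
centroid does not exceed the stored distance keeps its membership without
being compared to the other k-1 centroids; otherwise it is reassigned by a
full scan.

The two variants differ only in the cache-refresh policy for kept points:
Enhanced refreshes ``pointdis`` with the new (smaller or equal) distance,
Overlapped leaves it anchored at the distance recorded at the last full
reassignment.  The published descriptions do not pin the distinction down
further; this refresh-policy reading is a documented judgment call and
everything else is shared machinery.

Distance evaluations are counted exactly (one per shortcut check, plus k
per full scan) so that the claimed speedups can be audited rather than
timed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (
    AlgoConfig,
    CentroidSet,
    RunTrace,
    distance_matrix,
    init_centroids,
    mse,
    point_to_assigned,
    update_centroids,
)
from .io import DataMatrix, PartitionLabels


def _run_fahim(
    data: DataMatrix,
    config: AlgoConfig,
    refresh_kept: bool,
    audit: Optional[list] = None,
) -> tuple[PartitionLabels, CentroidSet, RunTrace]:
    if data.n < config.k:
        raise ValueError(f"n={data.n} < k={config.k}")
    X = data.values
    n, k = data.n, config.k
    kind = config.distance

    centroids = init_centroids(data, config)
    trace = RunTrace()

    # Iteration 1: full assignment, caches populated for every point.
    D = distance_matrix(X, centroids.means, kind)
    clusterid = D.argmin(axis=1)
    pointdis = D[np.arange(n), clusterid]
    cum_evals = n * k
    trace.append(1, mse(data, centroids, clusterid), n, 0, cum_evals)

    for i in range(2, config.max_iter + 1):
        centroids = update_centroids(data, clusterid, k, centroids)
        d_new = point_to_assigned(X, centroids.means, clusterid, kind)
        evals = n  # one shortcut check per point
        kept = d_new <= pointdis
        if audit is not None:
            audit.append(
                {
                    "iteration": i,
                    "d_new": d_new.copy(),
                    "pointdis_before": pointdis.copy(),
                    "kept": kept.copy(),
                }
            )
        new_labels = clusterid.copy()
        if refresh_kept:
            pointdis = np.where(kept, d_new, pointdis)
        lose = ~kept
        if lose.any():
            Dl = distance_matrix(X[lose], centroids.means, kind)
            evals += int(lose.sum()) * k
            nearest = Dl.argmin(axis=1)
            new_labels[lose] = nearest
            pointdis = pointdis.copy()
            pointdis[lose] = Dl[np.arange(Dl.shape[0]), nearest]
        moved = int((new_labels != clusterid).sum())
        clusterid = new_labels
        cum_evals += evals
        trace.append(i, mse(data, centroids, clusterid), moved, 0, cum_evals)
        if moved == 0:
            break

    centroids = update_centroids(data, clusterid, k, centroids)
    return PartitionLabels(ids=list(data.ids), labels=clusterid), centroids, trace


def run_enhanced(
    data: DataMatrix, config: AlgoConfig, audit: Optional[list] = None
) -> tuple[PartitionLabels, CentroidSet, RunTrace]:
    """Enhanced k-means: shortcut with cache refresh on kept points.

    If the distance from a point to the updated centroid of its current
    cluster is <= its stored distance, the point stays put and the stored
    distance is updated; otherwise all k centroids are scanned.  Pass an
    ``audit`` list to capture per-iteration shortcut decisions for
    soundness checking.
    """
    return _run_fahim(data, config, refresh_kept=True, audit=audit)


def run_overlapped(
    data: DataMatrix, config: AlgoConfig, audit: Optional[list] = None
) -> tuple[PartitionLabels, CentroidSet, RunTrace]:
    """Overlapped k-means: shortcut without cache refresh on kept points."""
    return _run_fahim(data, config, refresh_kept=False, audit=audit)
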