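"""Metric-matrices k-means: whole-cluster stability detection.

The mechanism rests on the spectral relation between PCA and the k-means
objective.  The optimal objective SSE_l is bounded below by
``||X||_F^2 - sum_{j=1}^{k} sigma_j^2`` where sigma_j are the largest
singular values of the data matrix X.  Dividing that bound by the
first-iteration objective SSE_1 gives a dimensionless multiplier
``m in [0, 1]`` and an estimate ``MSE_l ~ m * MSE_1`` of the optimal mean
squared error — obtainable after a single Lloyd pass, before the run has
converged.

Two devices are built on this estimate:

* **MMI detection** — the first iteration whose MSE comes within an
  epsilon-band of the estimated optimum (a Cauchy-style criterion) marks
  the switch-on point of the stability mechanism; the iteration index is
  additionally capped at ``ceil(MSE_1 * k / MSE_l_est)``.

* **Per-cluster freezing** — after MMI, each iteration builds the k x k
  "metric matrix" of Pearson correlations between the previous and current
  centroid sets.  When the j-th sorted eigenvalue of this matrix stops
  changing between iterations (relative change within the 0.5%--1.5%
  stability band), cluster j is declared stable and its members skip the
  assignment scan entirely.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    AlgoConfig,
    CentroidSet,
    RunTrace,
    _standardize_rows,
    assign_points,
    init_centroids,
    mse,
    update_centroids,
)
from .io import DataMatrix, PartitionLabels

logger = logging.getLogger(__name__)

_TINY = 1e-12


@dataclass
class MultiplierEstimate:
    """Spectral estimate of the optimal objective from iteration 1.

    Attributes
    ----------
    m : dimensionless multiplier, the spectral lower bound on the optimal
        SSE divided by the first-iteration SSE; always in [0, 1].
    sse1 : first-iteration sum of squared errors.
    frob_sq : squared Frobenius norm of the data matrix.
    sigma_sq : the k largest squared singular values of the data matrix
        (zero-padded past the rank).
    mse_l_est : estimated optimal MSE, ``m * sse1 / n`` = bound / n.
    n : number of points (to convert SSE <-> MSE).
    """

    m: float
    sse1: float
    frob_sq: float
    sigma_sq: np.ndarray
    mse_l_est: float
    n: int

    @property
    def mse1(self) -> float:
        return self.sse1 / self.n


@dataclass
class MetricMatrixRecord:
    """One iteration's metric matrix, eigenvalues, and stability verdicts.

    ``mm[i, j]`` is the Pearson correlation between previous-iteration
    centroid i and current-iteration centroid j.  Eigenvalues are taken
    from the symmetrized matrix and sorted descending; index j maps to
    cluster j through that sort order.  ``diff``/``diff_rel`` compare with
    the previous record's eigenvalues and are None on the bootstrap call.
    """

    mm: np.ndarray
    eigenvalues: np.ndarray
    prev_eigenvalues: Optional[np.ndarray]
    diff: Optional[np.ndarray]
    diff_rel: Optional[np.ndarray]
    stable: np.ndarray  # k booleans


@dataclass
class MMIState:
    """Detected switch-on iteration for the stability mechanism."""

    mmi: Optional[int]
    epsilon: float
    mode: str  # "relative" | "absolute"

    @property
    def detected(self) -> bool:
        return self.mmi is not None


def compute_multiplier(data: DataMatrix, k: int, sse1: float) -> MultiplierEstimate:
    """Estimate the optimal objective from the top-k spectrum of X.

    The k largest squared singular values are obtained from the smaller
    Gram matrix (d x d or n x n, whichever is cheaper); entries past the
    matrix rank count as zero, so k > min(n, d) simply drives the bound to
    0 and m to 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sse1 <= 0:
        raise ValueError("sse1 must be positive (degenerate data?)")
    X = data.values
    n, d = X.shape
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    frob_sq = float(np.einsum("ij,ij->", X, X))
    gram = X.T @ X if d <= n else X @ X.T
    ev = np.linalg.eigvalsh(gram)[::-1]  # descending
    ev = np.clip(ev, 0.0, None)
    sigma_sq = np.zeros(k)
    take = min(k, ev.size)
    sigma_sq[:take] = ev[:take]
    bound = max(0.0, frob_sq - float(sigma_sq.sum()))
    m = bound / sse1
    return MultiplierEstimate(
        m=m,
        sse1=float(sse1),
        frob_sq=frob_sq,
        sigma_sq=sigma_sq,
        mse_l_est=bound / n,
        n=n,
    )


def _mmi_bound(estimate: MultiplierEstimate, k: int) -> int:
    """Upper bound on the switch-on iteration: ceil(MSE_1 * k / MSE_l_est)."""
    return math.ceil(estimate.mse1 * k / max(estimate.mse_l_est, _TINY))


def _epsilon_effective(estimate: MultiplierEstimate, config: AlgoConfig) -> float:
    if config.epsilon_mode == "relative":
        return config.epsilon * estimate.mse1
    return config.epsilon


def _mmi_condition(i: int, mse_i: float, estimate: MultiplierEstimate,
                   config: AlgoConfig) -> bool:
    """True at the first iteration where the mechanism may switch on."""
    if abs(mse_i - estimate.mse_l_est) <= _epsilon_effective(estimate, config):
        return True
    return i >= _mmi_bound(estimate, config.k)


def detect_mmi(trace: RunTrace, estimate: MultiplierEstimate,
               config: AlgoConfig) -> MMIState:
    """Scan a recorded trace for the stability switch-on iteration.

    Returns the smallest iteration i with ``|MSE_i - MSE_l_est| <=``
    epsilon (relative mode scales epsilon by MSE_1), capped at
    ``ceil(MSE_1 * k / MSE_l_est)``; unset if the trace never qualifies.
    The same predicate is evaluated online during :func:`run_mmkmeans`, so
    an offline rescan of a run's trace reproduces its MMI.
    """
    if not trace.records:
        raise ValueError("trace must contain at least one iteration")
    mmi: Optional[int] = None
    for r in trace.records:
        if _mmi_condition(r.iteration, r.mse, estimate, config):
            mmi = r.iteration
            break
    return MMIState(mmi=mmi, epsilon=config.epsilon, mode=config.epsilon_mode)


def build_metric_matrix(prev: CentroidSet, curr: CentroidSet) -> np.ndarray:
    """k x k Pearson correlations between previous and current centroids.

    Entry (i, j) correlates previous centroid i with current centroid j.
    Zero-variance centroids contribute 0 entries (with a logged warning).
    """
    if prev.k != curr.k:
        raise ValueError(f"centroid count mismatch: {prev.k} != {curr.k}")
    if prev.means.shape[1] < 2:
        raise ValueError("metric matrix needs centroid dimension >= 2")
    P = _standardize_rows(prev.means)
    C = _standardize_rows(curr.means)
    return np.clip(P @ C.T, -1.0, 1.0)


def mm_eigenvalues(mm: np.ndarray) -> np.ndarray:
    """Eigenvalues of the symmetrized metric matrix, sorted descending.

    The correlation matrix between two *different* centroid sets is not
    symmetric in general, and a non-symmetric matrix can have complex
    eigenvalues; symmetrizing via (mm + mm.T)/2 guarantees a real, sortable
    spectrum and is exact whenever mm is already symmetric (the converged
    regime in which the stability test operates).
    """
    mm = np.asarray(mm, dtype=float)
    if mm.ndim != 2 or mm.shape[0] != mm.shape[1]:
        raise ValueError("metric matrix must be square")
    sym = (mm + mm.T) / 2.0
    return np.linalg.eigvalsh(sym)[::-1].copy()


def compute_mm_step(
    prev_record: Optional[MetricMatrixRecord],
    prev_c: CentroidSet,
    curr_c: CentroidSet,
    config: AlgoConfig,
) -> MetricMatrixRecord:
    """One stability-check step: correlate centroid sets, compare spectra.

    On the bootstrap call (``prev_record`` is None) there are no previous
    eigenvalues, so nothing can be declared stable.  Afterwards, cluster j
    is stable when the relative change of the j-th sorted eigenvalue is
    within the band: ``diff_rel <= H1`` in ``threshold`` mode (default;
    a fully converged cluster has diff ~ 0 and must count as stable) or
    ``L0 <= diff_rel <= H1`` in ``strict_interval`` mode (the literal
    band, which excludes fully converged clusters).
    """
    mm = build_metric_matrix(prev_c, curr_c)
    e = mm_eigenvalues(mm)
    k = e.size
    if prev_record is None:
        return MetricMatrixRecord(
            mm=mm, eigenvalues=e, prev_eigenvalues=None,
            diff=None, diff_rel=None, stable=np.zeros(k, dtype=bool),
        )
    pe = prev_record.eigenvalues
    if pe.size != k:
        raise ValueError("cluster count changed between records")
    diff = np.abs(e - pe)
    diff_rel = diff / np.maximum(np.abs(pe), _TINY)
    if config.stability_mode == "threshold":
        stable = diff_rel <= config.H1
    else:
        stable = (config.L0 <= diff_rel) & (diff_rel <= config.H1)
    return MetricMatrixRecord(
        mm=mm, eigenvalues=e, prev_eigenvalues=pe.copy(),
        diff=diff, diff_rel=diff_rel, stable=stable,
    )


def run_mmkmeans(
    data: DataMatrix, config: AlgoConfig
) -> tuple[PartitionLabels, CentroidSet, RunTrace, MMIState,
           list[MetricMatrixRecord]]:
    """Lloyd iterations with spectral whole-cluster freezing.

    The run proceeds exactly like Traditional k-means until the switch-on
    iteration MMI is detected (or taken from ``config.mmi_override``).
    From iteration MMI onward, each centroid update is followed by a
    metric-matrix stability check; members of stable clusters skip the
    next assignment scan, while every other point is still compared
    against all k centroids (frozen clusters may gain points).  The run
    stops when no point moves, when every cluster is stable, or at
    ``max_iter``.

    With ``mmi_override >= max_iter`` the mechanism never fires and the
    output is identical to :func:`core.run_traditional` under the same
    config.  Negative input values trigger a warning: the eigenvalue
    stability band was calibrated for non-negative expression values and
    is not guaranteed to behave well otherwise.
    """
    if data.n < config.k:
        raise ValueError(f"n={data.n} < k={config.k}")
    if data.d < 2:
        raise ValueError("the metric-matrix mechanism requires d >= 2")
    if (data.values < 0).any():
        warnings.warn(
            "input contains negative values; the eigenvalue stability band "
            "is calibrated for non-negative expression data",
            UserWarning,
            stacklevel=2,
        )

    k = config.k
    centroids = init_centroids(data, config)
    trace = RunTrace()
    labels: Optional[np.ndarray] = None
    frozen = np.zeros(k, dtype=bool)
    records: list[MetricMatrixRecord] = []
    prev_record: Optional[MetricMatrixRecord] = None
    estimate: Optional[MultiplierEstimate] = None
    mmi: Optional[int] = config.mmi_override
    cum_evals = 0

    for i in range(1, config.max_iter + 1):
        new_labels, moved, evals = assign_points(
            data, centroids, frozen, labels, config.distance
        )
        cum_evals += evals
        mse_i = mse(data, centroids, new_labels)
        labels = new_labels
        trace.append(i, mse_i, moved, int(frozen.sum()), cum_evals)

        if i == 1 and config.mmi_override is None and mse_i > 0:
            # mse_1 == 0 means the initial centroids already fit perfectly;
            # the run terminates immediately and no estimate is needed
            estimate = compute_multiplier(data, k, sse1=mse_i * data.n)
        if mmi is None and estimate is not None:
            if _mmi_condition(i, mse_i, estimate, config):
                mmi = i
                logger.info("MMI detected at iteration %d", mmi)

        if moved == 0:
            break
        prev_c = centroids
        centroids = update_centroids(data, labels, k, centroids)

        # "executed when the current total iterations number is greater
        # than MMI - 1": the check runs from iteration MMI onward.
        if mmi is not None and i >= mmi:
            prev_record = compute_mm_step(prev_record, prev_c, centroids, config)
            records.append(prev_record)
            frozen = prev_record.stable
            if frozen.all():
                break

    assert labels is not None
    centroids = update_centroids(data, labels, k, centroids)
    mmi_state = MMIState(mmi=mmi, epsilon=config.epsilon, mode=config.epsilon_mode)
    if not mmi_state.detected and config.mmi_override is None:
        logger.info("MMI never detected; run behaved as Traditional k-means")
    return (
        PartitionLabels(ids=list(data.ids), labels=labels),
        centroids,
        trace,
        mmi_state,
        records,
    )
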