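"""Partition agreement: the Hubert-Arabie adjusted Rand index.

ARI_HA corrects the Rand index for chance agreement: 0 is the expected
score of two independent random partitions, 1 is perfect agreement, and
negative values indicate less-than-chance agreement.  It is computed from
the contingency table of co-membership counts and is invariant to cluster
relabeling and symmetric in its arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PartitionLabels

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Co-membership counts between two partitions plus marginals."""

    counts: np.ndarray  # r x c, n_ij
    row_marginals: np.ndarray  # a_i
    col_marginals: np.ndarray  # b_j
    n: int


def _align(p: PartitionLabels, q: PartitionLabels) -> tuple[np.ndarray, np.ndarray]:
    """Return label arrays aligned by id; raise on mismatched id sets."""
    if p.ids == q.ids:
        return p.labels, q.labels
    if set(p.ids) != set(q.ids):
        raise ValueError("partitions cover different id sets")
    order = {rid: i for i, rid in enumerate(q.ids)}
    idx = np.array([order[rid] for rid in p.ids])
    return p.labels, q.labels[idx]


def contingency_table(p: PartitionLabels, q: PartitionLabels) -> ContingencyTable:
    """Build the r x c table of co-membership counts, aligned by id."""
    pl, ql = _align(p, q)
    pr = np.unique(pl, return_inverse=True)[1]
    qr = np.unique(ql, return_inverse=True)[1]
    r, c = pr.max() + 1, qr.max() + 1
    counts = np.zeros((r, c), dtype=np.int64)
    np.add.at(counts, (pr, qr), 1)
    return ContingencyTable(
        counts=counts,
        row_marginals=counts.sum(axis=1),
        col_marginals=counts.sum(axis=0),
        n=int(counts.sum()),
    )


def _pairs(x: np.ndarray) -> np.ndarray:
    """C(x, 2) elementwise."""
    x = x.astype(np.float64)
    return x * (x - 1.0) / 2.0


def ari_ha(p: PartitionLabels, q: PartitionLabels) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    ``(sum_ij C(n_ij,2) - E) / (0.5*[sum_i C(a_i,2) + sum_j C(b_j,2)] - E)``
    with ``E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2)``.

    Degenerate inputs where the denominator vanishes (both partitions a
    single cluster, or both all singletons) are not covered by the
    formula; by convention the function returns 1.0 when the two
    partitions are identical up to relabeling and 0.0 otherwise, and logs
    the event.
    """
    tab = contingency_table(p, q)
    if tab.n < 2:
        raise ValueError("ARI requires at least 2 points")
    sum_ij = _pairs(tab.counts).sum()
    sum_a = _pairs(tab.row_marginals).sum()
    sum_b = _pairs(tab.col_marginals).sum()
    total = _pairs(np.array([tab.n]))[0]
    expected = sum_a * sum_b / total
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        identical = (
            tab.counts.shape[0] == tab.counts.shape[1]
            and np.count_nonzero(tab.counts) == tab.counts.shape[0]
        )
        logger.warning(
            "ari_ha: degenerate partitions (denominator 0); returning %s by convention",
            1.0 if identical else 0.0,
        )
        return 1.0 if identical else 0.0
    return float((sum_ij - expected) / denom)


def compare_partitions_report(
    runs: dict[str, PartitionLabels], reference: str
) -> pd.DataFrame:
    """ARI of each algorithm's partition against a reference partition.

    Returns a one-column table ``ari_vs_<reference>`` with one row per
    non-reference algorithm, plus an ``enhanced_vs_overlapped`` row when
    both of those algorithms are present (mirroring the usual side-by-side
    layout of cluster-quality tables).
    """
    if reference not in runs:
        raise ValueError(f"reference {reference!r} not among runs {sorted(runs)}")
    ref = runs[reference]
    rows = {}
    for name, part in runs.items():
        if name == reference:
            continue
        rows[name] = ari_ha(part, ref)
    if "enhanced" in runs and "overlapped" in runs:
        rows["enhanced_vs_overlapped"] = ari_ha(runs["enhanced"], runs["overlapped"])
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"ari_vs_{reference}"]
    )
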