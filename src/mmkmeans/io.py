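"""Reading and writing expression matrices, partitions, and run traces.

The expression-matrix format is the tab-delimited layout common to
time-course microarray supplements: one row per gene, an identifier in the
first column, and one numeric column per timepoint.  Files may or may not
carry a header line; gaps (empty or non-numeric cells) are frequent in
spotted-array data and are handled by an explicit missing-value policy.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .core import RunTrace

logger = logging.getLogger(__name__)

NA_POLICIES = ("drop_row", "impute_row_mean")


@dataclass
class DataMatrix:
    """An n-by-d numeric matrix with one string identifier per row.

    Rows are the points to cluster (genes, samples, simulated points);
    columns are features (timepoints for expression data).  Values are
    unitless (log-ratios or arbitrary features).
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids for {self.values.shape[0]} rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("row ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class PartitionLabels:
    """Integer cluster assignment per row, aligned with a DataMatrix by id."""

    ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.ids) != self.labels.shape[0]:
            raise ValueError("one integer label per id required")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PartitionLabels):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.labels, other.labels)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _parse_cell(token: str) -> float:
    """Parse one data cell; empty or non-numeric cells become NaN."""
    token = token.strip()
    if not token:
        return math.nan
    try:
        return float(token)
    except ValueError:
        return math.nan


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    id_column: bool = True,
    na_policy: str = "drop_row",
) -> DataMatrix:
    """Read a delimited numeric matrix, one optional ID column first.

    Parameters
    ----------
    path
        File to read (UTF-8 text).
    delimiter
        Field separator, tab by default.
    id_column
        If True the first field of each row is a row identifier; otherwise
        identifiers ``row0, row1, ...`` are generated in file order.
    na_policy
        ``drop_row``: rows containing unparseable/empty cells, or with a
        deviant field count, are discarded (counts are logged).
        ``impute_row_mean``: missing cells are replaced by the mean of the
        row's finite cells; rows with a deviant field count raise.

    The dimensionality ``d`` is fixed by the first data row.  A first line
    whose would-be first numeric field is non-numeric is treated as a
    header and skipped.
    """
    path = Path(path)
    if na_policy not in NA_POLICIES:
        raise ValueError(f"na_policy must be one of {NA_POLICIES}")
    if not path.exists():
        raise FileNotFoundError(path)

    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if any(f.strip() for f in r)]

    if not rows:
        raise ValueError(f"{path}: no parseable rows")

    probe_idx = 1 if id_column else 0
    first = rows[0]
    if len(first) > probe_idx and not _is_number(first[probe_idx]):
        rows = rows[1:]  # header line
    if not rows:
        raise ValueError(f"{path}: no parseable rows after header")

    d = len(rows[0]) - (1 if id_column else 0)
    if d < 1:
        raise ValueError(f"{path}: first data row has no numeric columns")

    ids: list[str] = []
    out: list[np.ndarray] = []
    dropped = imputed = 0
    for i, row in enumerate(rows):
        rid = row[0].strip() if id_column else f"row{i}"
        fields = row[1:] if id_column else row
        if len(fields) != d:
            if na_policy == "drop_row":
                dropped += 1
                continue
            raise ValueError(
                f"{path}: row {i} has {len(fields)} columns, expected {d} "
                "(ragged rows are not allowed under impute_row_mean)"
            )
        vals = np.array([_parse_cell(f) for f in fields])
        bad = ~np.isfinite(vals)
        if bad.any():
            if na_policy == "drop_row":
                dropped += 1
                continue
            good = vals[~bad]
            if good.size == 0:
                dropped += 1  # nothing to impute from
                continue
            vals[bad] = good.mean()
            imputed += 1
        ids.append(rid)
        out.append(vals)

    if dropped or imputed:
        logger.info(
            "%s: kept %d rows, dropped %d, imputed %d", path, len(out), dropped, imputed
        )
    if not out:
        raise ValueError(f"{path}: zero parseable rows")
    return DataMatrix(ids=ids, values=np.vstack(out))


def write_partition(path: str | Path, labels: PartitionLabels) -> None:
    """Write a two-column TSV ``id<TAB>cluster`` with a header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tcluster\n")
        for rid, lab in zip(labels.ids, labels.labels):
            fh.write(f"{rid}\t{int(lab)}\n")


def read_partition(path: str | Path) -> PartitionLabels:
    """Read a partition TSV written by :func:`write_partition`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: list[str] = []
    labs: list[int] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise ValueError(f"{path}: missing 'id<TAB>cluster' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            try:
                labs.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer label {parts[1]!r}") from exc
            ids.append(parts[0])
    return PartitionLabels(ids=ids, labels=np.array(labs, dtype=int))


def write_trace(path: str | Path, trace: "RunTrace") -> None:
    """Write per-iteration diagnostics as TSV.

    Columns: iteration, mse, moved, stable_clusters, dist_evals (cumulative).
    MSE is written with 12 significant digits.
    """
    records = trace.records
    if not records:
        raise ValueError("cannot write an empty trace")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("iteration\tmse\tmoved\tstable_clusters\tdist_evals\n")
        for r in records:
            fh.write(
                f"{r.iteration}\t{r.mse:.12g}\t{r.moved}\t{r.stable_clusters}\t{r.dist_evals}\n"
            )
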