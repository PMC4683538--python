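"""Core data containers, discretization and expression-matrix I/O.

A gene-expression time course is held as an ``N × (T+1)`` matrix: ``N``
variables (genes) observed at time points ``0..T``.  Time point 0 only ever
appears as a conditioning slice — every modelled transition is
``x(t-1) -> x(t)`` for ``t = 1..T`` — so a series must contain at least two
columns.  Discrete state spaces are per-variable: variable ``i`` takes
values in ``{0, .., r_i - 1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousTimeSeries",
    "DiscreteTimeSeries",
    "ExpressionFormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "binarize",
    "parent_config_index",
    "parent_config_table",
]


class ExpressionFormatError(ValueError):
    """Raised for malformed expression-matrix files (ragged rows, bad cells)."""


@dataclass
class ContinuousTimeSeries:
    """Real-valued expression matrix, genes × time points."""

    values: np.ndarray
    var_names: list[str]
    time_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes × time)")
        if len(self.var_names) != self.values.shape[0]:
            raise ValueError("var_names length does not match row count")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.var_names[bad[0]]!r}, "
                f"time column {bad[1]}"
            )

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class DiscreteTimeSeries:
    """Discrete expression matrix with per-variable arities.

    ``values[i, t]`` is the state of variable ``i`` at time ``t`` and must
    lie in ``[0, arities[i])``.  ``T = n_times - 1`` is the number of
    observed transitions.
    """

    values: np.ndarray
    var_names: list[str]
    arities: list[int] = field(default=None)  # type: ignore[assignment]
    time_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("state matrix must be 2-D (variables × time)")
        n, t1 = self.values.shape
        if n < 1:
            raise ValueError("need at least one variable")
        if t1 < 2:
            raise ValueError("need at least two time points (one transition)")
        if len(self.var_names) != n:
            raise ValueError("var_names length does not match row count")
        if self.arities is None:
            self.arities = [int(row.max()) + 1 for row in self.values]
        self.arities = [max(int(r), 2) for r in self.arities]
        for i, r in enumerate(self.arities):
            row = self.values[i]
            if row.min() < 0 or row.max() >= r:
                raise ValueError(
                    f"state out of range for variable {self.var_names[i]!r}: "
                    f"values must lie in [0, {r})"
                )

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def n_transitions(self) -> int:
        """T: number of modelled transitions t-1 → t."""
        return self.values.shape[1] - 1


def read_expression_tsv(path: str | Path) -> ContinuousTimeSeries:
    """Read a genes × time-points TSV (header row of time labels, first
    column of gene names) into a :class:`ContinuousTimeSeries`.

    Raises :class:`ExpressionFormatError` for ragged rows, and a parse error
    naming the offending cell for non-numeric or missing entries.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ExpressionFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    time_labels = [c.strip() for c in header[1:]]
    width = len(header)
    names: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != width:
            raise ExpressionFormatError(
                f"{path}: ragged row at line {lineno}: expected {width} "
                f"columns, got {len(cells)}"
            )
        names.append(cells[0].strip())
        parsed: list[float] = []
        for col, cell in enumerate(cells[1:], start=1):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                raise ExpressionFormatError(
                    f"{path}: missing value at line {lineno}, column "
                    f"{col + 1} (gene {cells[0]!r}, time {time_labels[col - 1]!r})"
                )
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ExpressionFormatError(
                    f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                    f"column {col + 1}"
                ) from None
        rows.append(parsed)
    if not rows:
        raise ExpressionFormatError(f"{path}: no data rows")
    return ContinuousTimeSeries(np.array(rows, dtype=float), names, time_labels)


def write_expression_tsv(series: ContinuousTimeSeries | DiscreteTimeSeries,
                         path: str | Path) -> None:
    """Write a series back to TSV; integer matrices round-trip bit-exactly."""
    path = Path(path)
    labels = series.time_labels or [str(t) for t in range(series.values.shape[1])]
    df = pd.DataFrame(series.values, index=series.var_names, columns=labels)
    if np.issubdtype(series.values.dtype, np.integer):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="gene")


def binarize(data: ContinuousTimeSeries,
             method: str = "per-gene-mean") -> DiscreteTimeSeries:
    """Threshold each gene at its own mean (or median) into {0, 1}.

    ``x_i(t) = 1`` iff the raw value strictly exceeds the per-gene
    threshold.  Constant genes map to all-zero with a warning.
    """
    if data.values.size == 0:
        raise ValueError("cannot binarize an empty matrix")
    if method == "per-gene-mean":
        thresh = data.values.mean(axis=1, keepdims=True)
    elif method == "per-gene-median":
        thresh = np.median(data.values, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    const = np.ptp(data.values, axis=1) == 0
    if const.any():
        names = [data.var_names[i] for i in np.flatnonzero(const)]
        warnings.warn(
            f"constant expression rows mapped to all-0: {', '.join(names)}",
            stacklevel=2,
        )
    states = (data.values > thresh).astype(np.int64)
    return DiscreteTimeSeries(
        states, list(data.var_names), [2] * data.n_vars, data.time_labels
    )


def parent_config_index(states: Sequence[int],
                        parent_arities: Sequence[int]) -> int:
    """Mixed-radix index of a joint parent-state tuple.

    The first parent is the most significant digit; the empty parent set
    always maps to configuration 0.  Bijective onto ``[0, Π arities)``.
    """
    if len(states) != len(parent_arities):
        raise ValueError("one state per parent required")
    j = 0
    for s, r in zip(states, parent_arities):
        s = int(s)
        if not 0 <= s < r:
            raise ValueError(f"parent state {s} out of range [0, {r})")
        j = j * int(r) + s
    return j


def parent_config_table(data: DiscreteTimeSeries,
                        parents: Sequence[int]) -> tuple[np.ndarray, int]:
    """Vector of parent-configuration indices ``j(t-1)`` for ``t = 1..T``.

    Returns ``(jidx, q)`` where ``jidx`` has length T and ``q`` is the
    number of joint parent configurations.  With no parents ``jidx`` is all
    zeros and ``q = 1``.
    """
    T = data.n_transitions
    jidx = np.zeros(T, dtype=np.int64)
    q = 1
    for p in parents:
        r = data.arities[p]
        jidx = jidx * r + data.values[p, :-1]
        q *= r
    return jidx, q
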