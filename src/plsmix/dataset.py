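"""Time-series expression dataset container and tabular reader/writer.

The basic data object is a rectangular matrix of N entities (genes,
transcripts, proteins) measured at M time points.  Time stamps are real
numbers in whatever unit the experiment used (seconds, minutes, hours);
they need not be equally spaced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["TimeSeriesDataset", "read_expression_matrix", "write_expression_matrix"]


@dataclass(frozen=True)
class TimeSeriesDataset:
    """N entity profiles observed at M shared time points.

    Parameters
    ----------
    identifiers
        Unique entity names, in file/row order.
    values
        N x M float matrix of measurements (typically log-ratios).
    timestamps
        M strictly increasing real time stamps.
    """

    identifiers: list[str]
    values: np.ndarray
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = values.shape
        if n < 1 or m < 2:
            raise ValueError(f"need at least 1 entity and 2 time points, got {n}x{m}")
        if len(self.identifiers) != n:
            raise ValueError("identifier count does not match number of rows")
        seen: set[str] = set()
        for ident in self.identifiers:
            if ident in seen:
                raise ValueError(f"duplicate identifier: {ident!r}")
            seen.add(ident)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value for {self.identifiers[i]!r} at time point {j + 1}"
            )
        ts = self.timestamps
        if ts is None:
            ts = np.arange(1, m + 1, dtype=float)
        ts = np.asarray(ts, dtype=float)
        if ts.shape != (m,):
            raise ValueError("timestamps length does not match number of columns")
        if not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "identifiers", list(self.identifiers))

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def index_of(self, identifier: str) -> int:
        return self.identifiers.index(identifier)


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\r").split("\t")


def read_expression_matrix(path: str | Path) -> TimeSeriesDataset:
    """Read a tab-separated expression matrix.

    Layout: a header row whose cells after the first give the time stamps,
    then one row per entity (identifier, then M values).  Lines starting
    with ``#`` are comments.  If the header cells are not all numeric the
    time stamps fall back to the indices 1..M and a warning is logged.
    Duplicate identifiers, ragged rows, missing or non-numeric values are
    rejected.
    """
    path = Path(path)
    header: list[str] | None = None
    identifiers: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            fields = _split_fields(raw)
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path.name}:{lineno}: row has {len(fields)} fields, "
                    f"expected {len(header)}"
                )
            ident = fields[0]
            if ident in set(identifiers):
                raise ValueError(f"{path.name}:{lineno}: duplicate identifier {ident!r}")
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric value cell ({exc})")
            identifiers.append(ident)
    if header is None or not rows:
        raise ValueError(f"{path.name}: no data rows found")
    m = len(header) - 1
    try:
        timestamps = np.array([float(c) for c in header[1:]], dtype=float)
    except ValueError:
        logger.warning(
            "%s: non-numeric header cells; using time-point indices 1..%d", path.name, m
        )
        timestamps = np.arange(1, m + 1, dtype=float)
    return TimeSeriesDataset(identifiers, np.array(rows, dtype=float), timestamps)


def write_expression_matrix(dataset: TimeSeriesDataset, path: str | Path) -> None:
    """Write a dataset in the same TSV layout ``read_expression_matrix`` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(f"{t:.17g}" for t in dataset.timestamps) + "\n")
        for ident, row in zip(dataset.identifiers, dataset.values):
            fh.write(ident + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
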