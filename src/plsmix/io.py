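"""Readers and writers for the pipeline's tabular artifacts.

All artifacts are plain TSV: decimal point only, ``#`` comment lines
ignored, no locale handling.  Round-trips reproduce values to full stored
precision and never reorder entities.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .dataset import read_expression_matrix, write_expression_matrix
from .inference import SimilarityMatrix

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "write_clusters",
    "read_clusters",
    "write_enrichment_table",
]


def write_similarity_matrix(
    matrix: SimilarityMatrix, identifiers: list[str], path: str | Path
) -> None:
    """Write an N x N similarity matrix as TSV (header row = identifiers)."""
    values = matrix.values
    if values.shape[0] != len(identifiers):
        raise ValueError("identifier count does not match matrix size")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(identifiers) + "\n")
        for ident, row in zip(identifiers, values):
            fh.write(ident + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_similarity_matrix(path: str | Path) -> tuple[SimilarityMatrix, list[str]]:
    """Read a similarity matrix written by :func:`write_similarity_matrix`.

    Asymmetric matrices, entries outside [0, 1] or a diagonal differing
    from 1 are rejected.
    """
    path = Path(path)
    identifiers: list[str] = []
    rows: list[list[float]] = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if header is None:
                header = fields[1:]
                continue
            identifiers.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric entry ({exc})")
    if header is None:
        raise ValueError(f"{path.name}: empty file")
    if identifiers != header:
        raise ValueError(f"{path.name}: row order differs from header order")
    values = np.array(rows, dtype=float)
    return SimilarityMatrix(values), identifiers


def write_clusters(
    clusters: ClusterSet, identifiers: list[str], path: str | Path
) -> None:
    """One cluster per line: cluster_id TAB comma-separated member names.

    Overlapping membership appears as repetition of a name across lines.
    """
    path = Path(path)
    with path.open("w") as fh:
        for k, members in enumerate(clusters.clusters):
            names = ",".join(identifiers[i] for i in members)
            fh.write(f"C{k + 1}\t{names}\n")


def read_clusters(
    path: str | Path, identifiers: list[str],
    merge_threshold: float = float("nan"), extension_threshold: float = float("nan"),
) -> ClusterSet:
    """Read a cluster file back into entity-index clusters."""
    index = {name: i for i, name in enumerate(identifiers)}
    out: list[tuple[int, ...]] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 tab-separated fields")
            try:
                members = tuple(sorted(index[name] for name in fields[1].split(",")))
            except KeyError as exc:
                raise ValueError(f"{path.name}:{lineno}: unknown identifier {exc}")
            out.append(members)
    return ClusterSet(tuple(out), merge_threshold, extension_threshold)


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
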