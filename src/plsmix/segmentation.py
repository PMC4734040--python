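"""Temporal segmentation of time points and the piecewise-linear design matrix.

A piecewise linear sequence (PLS) describes a trajectory over M time points
as straight-line pieces on S contiguous time segments, with discontinuous
"jumps" allowed between consecutive segments.  The parameter vector is
ordered

    (init, slope_1, jump_2, slope_2, ..., jump_S, slope_S)

so a model with S segments has L = 2S parameters.  The design matrix C maps
a parameter vector to the M per-time-point means; every profile is then
modelled as x = C mu + noise.

Segments are chosen either manually or semi-automatically: time points whose
value vectors (across all entities) behave similarly are grouped by
average-linkage hierarchical clustering, the dendrogram is cut at a
user-chosen threshold, and each group is split into maximal runs of
consecutive time indices so that segments stay contiguous in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .dataset import TimeSeriesDataset

__all__ = [
    "Segmentation",
    "PLSModel",
    "timepoint_distance_matrix",
    "segment_timepoints",
    "threshold_sweep",
    "parse_manual_segmentation",
    "build_design_matrix",
    "write_pls_model",
    "read_pls_model",
]


@dataclass(frozen=True)
class Segmentation:
    """Ordered contiguous segments covering time-point indices 0..M-1.

    ``segments`` holds (start, stop) half-open index ranges; consecutive
    ranges must abut so the union is exactly 0..M-1.
    """

    segments: tuple[tuple[int, int], ...]
    threshold_used: float | str = "manual"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segmentation needs at least one segment")
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        if segs[0][0] != 0:
            raise ValueError("first segment must start at the first time point")
        for (a, b), (c, _) in zip(segs, segs[1:]):
            if b != c:
                raise ValueError("segments must be contiguous and non-overlapping")
        for a, b in segs:
            if b <= a:
                raise ValueError("empty segment")
        object.__setattr__(self, "segments", segs)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_timepoints(self) -> int:
        return self.segments[-1][1]

    def segment_of(self, m: int) -> int:
        """Index of the segment containing time point ``m``."""
        for s, (a, b) in enumerate(self.segments):
            if a <= m < b:
                return s
        raise IndexError(m)

    def __str__(self) -> str:
        return ";".join(
            f"{a + 1}" if b == a + 1 else f"{a + 1}-{b}" for a, b in self.segments
        )


@dataclass(frozen=True)
class PLSModel:
    """A segmentation plus the M x L design matrix C built from it.

    ``column_map`` labels each retained column of C: ``init``, ``slope_<s>``
    or ``jump_<s>`` with 1-based segment numbers.  Columns of C that would
    be identically zero (the slope of a single-time-point segment) are
    pruned so C keeps full column rank.
    """

    segmentation: Segmentation
    timestamps: np.ndarray
    C: np.ndarray
    column_map: tuple[str, ...]

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        C = np.asarray(self.C, dtype=float)
        if C.shape != (ts.size, len(self.column_map)):
            raise ValueError("design matrix shape disagrees with labels/timestamps")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "column_map", tuple(self.column_map))

    @property
    def n_timepoints(self) -> int:
        return self.C.shape[0]

    @property
    def n_params(self) -> int:
        return self.C.shape[1]

    def prior_variances(self, v_init: float, v_jump: float, v_slope: float) -> np.ndarray:
        """Diagonal of the parameter prior covariance, ordered as column_map."""
        lookup = {"init": v_init, "jump": v_jump, "slope": v_slope}
        return np.array([lookup[lab.split("_")[0]] for lab in self.column_map])


def timepoint_distance_matrix(dataset: TimeSeriesDataset) -> np.ndarray:
    """M x M Euclidean distances between time-point value vectors.

    Entry (p, q) is the distance between the N-vectors of all entities'
    values at time points p and q; this is the dissimilarity used to group
    time points into candidate segments.
    """
    return squareform(pdist(dataset.values.T, metric="euclidean"))


def _cut_average_linkage(distances: np.ndarray, threshold: float) -> list[list[int]]:
    """Groups from average-linkage clustering, accepting merges below threshold."""
    m = distances.shape[0]
    if m == 1:
        return [[0]]
    Z = linkage(squareform(distances, checks=False), method="average")
    # Union-find over accepted merges; merge node ids follow scipy convention.
    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    for step, (left, right, height, _) in enumerate(Z):
        if height < threshold:
            node = m + step
            members[node] = members.pop(int(left)) + members.pop(int(right))
        else:
            break
    return [sorted(g) for g in members.values()]


def _contiguous_runs(indices: list[int]) -> list[tuple[int, int]]:
    runs = []
    start = prev = indices[0]
    for i in indices[1:]:
        if i != prev + 1:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def segment_timepoints(distances: np.ndarray, threshold: float) -> Segmentation:
    """Cut the average-linkage dendrogram of time points at ``threshold``.

    Dendrogram merges with height strictly below the threshold are accepted;
    the resulting groups are then split into maximal runs of consecutive
    time indices, because a PLS segment must be contiguous in time even when
    unconstrained clustering groups non-adjacent time points.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    distances = np.asarray(distances, dtype=float)
    segments: list[tuple[int, int]] = []
    for group in _cut_average_linkage(distances, threshold):
        segments.extend(_contiguous_runs(group))
    segments.sort()
    return Segmentation(tuple(segments), threshold_used=float(threshold))


def threshold_sweep(distances: np.ndarray) -> list[tuple[float, Segmentation]]:
    """Segmentation at every candidate threshold (each distinct merge height).

    Supports choosing a segmentation threshold by tracing how the grouping
    changes as the cut moves up the dendrogram.  Returns (threshold,
    segmentation) pairs where each threshold sits just above a distinct
    merge height.
    """
    distances = np.asarray(distances, dtype=float)
    m = distances.shape[0]
    if m == 1:
        return [(0.0, Segmentation(((0, 1),), threshold_used=0.0))]
    Z = linkage(squareform(distances, checks=False), method="average")
    heights = sorted(set(Z[:, 2]))
    candidates = [0.0] + [np.nextafter(h, np.inf) for h in heights]
    return [(t, segment_timepoints(distances, t)) for t in candidates]


def parse_manual_segmentation(text: str, n_timepoints: int) -> Segmentation:
    """Parse ``"1;2-4;5-8"`` style 1-based inclusive segment ranges."""
    segments = []
    for token in text.split(";"):
        token = token.strip()
        if "-" in token:
            a, b = token.split("-")
            segments.append((int(a) - 1, int(b)))
        else:
            segments.append((int(token) - 1, int(token)))
    seg = Segmentation(tuple(segments), threshold_used="manual")
    if seg.n_timepoints != n_timepoints:
        raise ValueError(
            f"manual segmentation covers {seg.n_timepoints} time points, "
            f"dataset has {n_timepoints}"
        )
    return seg


def build_design_matrix(segmentation: Segmentation, timestamps: np.ndarray) -> PLSModel:
    """Build the M x L design matrix for a segmentation over real time stamps.

    Row m (in segment s, 0-based) encodes the piecewise-linear evaluation

        value = init + sum_{r<=s, r>=1} jump_r
                     + sum_{r<s} slope_r * (t_end(r) - t_start(r))
                     + slope_s * (t_m - t_start(s))

    where t_start/t_end are the time stamps of a segment's first and last
    points.  Slopes multiply real time offsets, so unequal sampling is
    respected.  Identically zero columns are pruned.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if not np.all(np.diff(timestamps) > 0):
        raise ValueError("timestamps must be strictly increasing")
    m_points = timestamps.size
    if segmentation.n_timepoints != m_points:
        raise ValueError("segmentation does not cover the timestamps")
    s_count = segmentation.n_segments
    labels = ["init", "slope_1"]
    for s in range(2, s_count + 1):
        labels += [f"jump_{s}", f"slope_{s}"]
    col = {lab: j for j, lab in enumerate(labels)}
    C = np.zeros((m_points, len(labels)))
    starts = [timestamps[a] for a, _ in segmentation.segments]
    ends = [timestamps[b - 1] for _, b in segmentation.segments]
    for m in range(m_points):
        s = segmentation.segment_of(m)
        C[m, col["init"]] = 1.0
        for r in range(2, s + 2):
            C[m, col[f"jump_{r}"]] = 1.0
        for r in range(1, s + 1):
            C[m, col[f"slope_{r}"]] = ends[r - 1] - starts[r - 1]
        C[m, col[f"slope_{s + 1}"]] = timestamps[m] - starts[s]
    keep = [j for j in range(C.shape[1]) if np.any(C[:, j] != 0.0)]
    return PLSModel(
        segmentation=segmentation,
        timestamps=timestamps,
        C=C[:, keep],
        column_map=tuple(labels[j] for j in keep),
    )


def write_pls_model(model: PLSModel, path: str | Path) -> None:
    doc = {
        "segments": [[a + 1, b] for a, b in model.segmentation.segments],
        "threshold_used": model.segmentation.threshold_used,
        "timestamps": model.timestamps.tolist(),
        "column_map": list(model.column_map),
        "C": model.C.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_pls_model(path: str | Path) -> PLSModel:
    doc = json.loads(Path(path).read_text())
    seg = Segmentation(
        tuple((a - 1, b) for a, b in doc["segments"]),
        threshold_used=doc.get("threshold_used", "manual"),
    )
    return PLSModel(
        segmentation=seg,
        timestamps=np.asarray(doc["timestamps"], dtype=float),
        C=np.asarray(doc["C"], dtype=float),
        column_map=tuple(doc["column_map"]),
    )
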