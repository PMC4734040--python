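"""Two-stage clustering of the posterior co-clustering matrix.

Stage 1 (merge) greedily merges singleton clusters under complete linkage:
the link between two clusters is the *minimum* pairwise similarity between
their members, and the pair with the maximal link is merged while that link
stays at or above the merge threshold ``m``.  Stage 2 (extension) then
greedily adds outside entities to clusters: the affinity of entity j for
cluster S is ``min_{i in S} M_ij``, and the best (cluster, entity) pair is
extended while its affinity stays at or above the extension threshold
``e``.  An entity may be added to several clusters, so stage 2 is what
produces overlapping clusters.  Ties are broken lexicographically by
smallest member index, which makes the output deterministic even though
similarity values (integer multiples of one over the retained sample
count) tie frequently in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .dataset import TimeSeriesDataset
from .inference import SimilarityMatrix

__all__ = [
    "ClusterSet",
    "merge_stage",
    "extension_stage",
    "two_stage_cluster",
    "cluster_metrics",
    "adjusted_rand_index",
]


@dataclass(frozen=True)
class ClusterSet:
    """Possibly overlapping clusters of entity indices.

    ``clusters`` holds sorted index tuples, deduplicated, in the order they
    were produced.  Stage 1 output is a covering partition and stage 2 only
    adds members, so the union of clusters is always the full entity set.
    """

    clusters: tuple[tuple[int, ...], ...]
    merge_threshold: float
    extension_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def singletons(self) -> tuple[tuple[int, ...], ...]:
        return tuple(c for c in self.clusters if len(c) == 1)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    @property
    def largest_size(self) -> int:
        return max(len(c) for c in self.clusters)

    def membership_labels(self) -> np.ndarray:
        """First-membership labels per entity (for partition comparisons).

        Only well defined as a partition when clusters do not overlap, as
        after stage 1; with overlaps the first containing cluster wins.
        """
        n = max(max(c) for c in self.clusters) + 1
        labels = np.full(n, -1, dtype=int)
        for k, members in enumerate(self.clusters):
            for i in members:
                if labels[i] < 0:
                    labels[i] = k
        return labels


def _check_similarity(matrix) -> np.ndarray:
    if isinstance(matrix, SimilarityMatrix):
        return matrix.values
    return SimilarityMatrix(np.asarray(matrix, dtype=float)).values


def merge_stage(matrix, m: float) -> list[list[int]]:
    """Stage 1: complete-linkage greedy merging from singletons.

    Returns a partition (list of sorted member lists, ordered by smallest
    member).  Merging continues while the best inter-cluster link (minimum
    similarity over member pairs) is at least ``m``; ties are broken by the
    smallest (min index of first cluster, min index of second cluster) pair.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError("merge threshold must lie in [0, 1]")
    sim = _check_similarity(matrix)
    n = sim.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    # link[a][b] = complete-linkage similarity between clusters keyed by
    # their smallest member; symmetric, maintained under merges.
    link = {a: {b: sim[a, b] for b in range(n) if b != a} for a in range(n)}
    while len(clusters) > 1:
        best: tuple[float, int, int] | None = None
        for a in clusters:
            for b, val in link[a].items():
                if b <= a:
                    continue
                if best is None or val > best[0] or (val == best[0] and (a, b) < best[1:]):
                    best = (val, a, b)
        assert best is not None
        val, a, b = best
        if val < m:
            break
        clusters[a] = sorted(clusters[a] + clusters.pop(b))
        del link[a][b]
        del link[b]
        for c in clusters:
            if c == a:
                continue
            merged = min(link[a][c], link[c].pop(b))
            link[a][c] = merged
            link[c][a] = merged
    return [clusters[key] for key in sorted(clusters)]


def extension_stage(partition: list[list[int]], matrix, e: float) -> ClusterSet:
    """Stage 2: greedy extension of clusters by outside entities.

    The affinity of an outside entity j for cluster S is ``min_{i in S}
    M_ij``; the maximal (cluster, entity) pair is extended while its
    affinity is at least ``e``.  Entities already in other clusters remain
    candidates, which is how overlapping clusters arise.  Duplicate
    clusters produced by extension are dropped at the end.
    """
    if not (0.0 <= e <= 1.0):
        raise ValueError("extension threshold must lie in [0, 1]")
    sim = _check_similarity(matrix)
    n = sim.shape[0]
    covered = sorted({i for c in partition for i in c})
    if covered != list(range(n)):
        raise ValueError("partition must cover all entities")
    members: list[set[int]] = [set(c) for c in partition]
    # affinity[c] = per-entity min similarity to cluster c's members
    affinity: list[np.ndarray] = [np.min(sim[sorted(c), :], axis=0) for c in members]
    order_key = [min(c) for c in members]
    while True:
        best: tuple[float, int, int] | None = None
        for c, (mem, aff) in enumerate(zip(members, affinity)):
            for j in range(n):
                if j in mem:
                    continue
                val = aff[j]
                key = (order_key[c], j)
                if best is None or val > best[0] or (val == best[0] and key < (order_key[best[1]], best[2])):
                    best = (val, c, j)
        if best is None or best[0] < e:
            break
        _, c, j = best
        members[c].add(j)
        affinity[c] = np.minimum(affinity[c], sim[j, :])
        order_key[c] = min(order_key[c], j)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for mem in members:
        tup = tuple(sorted(mem))
        if tup not in seen:
            seen.add(tup)
            out.append(tup)
    return ClusterSet(tuple(out), merge_threshold=float("nan"), extension_threshold=e)


def two_stage_cluster(matrix, m: float = 0.5, e: float = 0.5) -> ClusterSet:
    """Merge then extend: the full deterministic clustering of a similarity
    matrix with merge threshold ``m`` and extension threshold ``e`` (both
    default 0.5)."""
    partition = merge_stage(matrix, m)
    result = extension_stage(partition, matrix, e)
    return ClusterSet(result.clusters, merge_threshold=m, extension_threshold=e)


def cluster_metrics(clusters: ClusterSet, dataset: TimeSeriesDataset) -> dict:
    """Internal cluster-quality measures on profile space.

    Returns the Davies-Bouldin index (centroid = mean member profile,
    scatter = mean Euclidean distance of members to the centroid; lower is
    better; ``None`` with fewer than two clusters), plus the mean
    intra-cluster and mean inter-cluster pairwise profile distances.  A
    singleton cluster has intra-cluster distance 0.
    """
    X = dataset.values
    groups = [np.asarray(c, dtype=int) for c in clusters.clusters]
    centroids = np.array([X[g].mean(axis=0) for g in groups])
    scatters = np.array(
        [float(np.mean(np.linalg.norm(X[g] - c, axis=1))) for g, c in zip(groups, centroids)]
    )
    k = len(groups)
    dbi = None
    if k >= 2:
        ratios = np.zeros(k)
        for i in range(k):
            worst = 0.0
            for j in range(k):
                if j == i:
                    continue
                sep = float(np.linalg.norm(centroids[i] - centroids[j]))
                val = (scatters[i] + scatters[j]) / sep if sep > 0 else np.inf
                worst = max(worst, val)
            ratios[i] = worst
        dbi = float(np.mean(ratios))

    def mean_pairwise(a: np.ndarray, b: np.ndarray | None = None) -> float:
        if b is None:
            if a.shape[0] < 2:
                return 0.0
            d = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=2)
            return float(np.sum(np.triu(d, 1)) / (a.shape[0] * (a.shape[0] - 1) / 2))
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        return float(np.mean(d))

    intra = float(np.mean([mean_pairwise(X[g]) for g in groups]))
    if k >= 2:
        inter_vals = [
            mean_pairwise(X[groups[i]], X[groups[j]])
            for i in range(k)
            for j in range(i + 1, k)
        ]
        inter = float(np.mean(inter_vals))
    else:
        inter = None
    return {
        "davies_bouldin": dbi,
        "mean_intra_cluster_distance": intra,
        "mean_inter_cluster_distance": inter,
        "n_clusters": k,
        "n_singletons": clusters.n_singletons,
        "largest_cluster_size": clusters.largest_size,
    }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (label vectors)."""
    return float(adjusted_rand_score(labels_a, labels_b))
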