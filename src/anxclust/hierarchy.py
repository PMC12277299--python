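"""Agglomerative hierarchical clustering from pairwise Euclidean distances.

The engine is written from scratch: a naive O(n^3) agglomeration driven by
the Lance-Williams recurrence. At country scale (n = 56) this is instant,
and the explicit merge loop keeps every tie-break and height auditable.

Node ids follow the SciPy convention: leaves are 0..n-1, the cluster formed
by merge step t gets id n + t. Heights are linkage distances; for Ward the
recurrence runs on squared distances and the recorded height is the square
root, which makes exported dendrograms directly comparable to standard
implementations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

LINKAGES = ("ward", "complete", "average", "single")

__all__ = [
    "LINKAGES",
    "DistanceMatrix",
    "Merge",
    "Dendrogram",
    "Partition",
    "pairwise_euclidean",
    "distance_matrix",
    "agglomerate",
    "cut_to_k",
    "cut_at_fraction",
    "export_dendrogram",
    "dendrogram_from_json",
]


class ClusteringError(ValueError):
    """Raised for invalid clustering inputs (bad linkage, k out of range, ...)."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise Euclidean distances between labelled points.

    `features` optionally keeps the (n, p) coordinates the distances came
    from; when present, agglomeration uses cluster centroids to break ties
    between equally close cluster pairs (see `agglomerate`).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ClusteringError(f"distance matrix shape {v.shape} does not match {n} labels")
        if not np.all(np.isfinite(v)):
            raise ClusteringError("distance matrix contains non-finite values")
        if np.any(v < 0) or not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ClusteringError("distance matrix must be symmetric, non-negative, zero-diagonal")
        if self.features is not None:
            f = np.asarray(self.features, dtype=float)
            if f.shape[0] != n:
                raise ClusteringError("features must have one row per label")
            object.__setattr__(self, "features", f)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: clusters `left` and `right` join at `height`."""

    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class Dendrogram:
    """Full merge history of an agglomerative clustering run."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ClusteringError(f"dendrogram needs exactly {n - 1} merges, got {len(self.merges)}")
        consumed: set[int] = set()
        for step, m in enumerate(self.merges):
            for node in (m.left, m.right):
                if node in consumed or node >= n + step:
                    raise ClusteringError(f"node {node} reused or out of order at step {step}")
                consumed.add(node)
        if self.merges and self.merges[-1].size != n:
            raise ClusteringError("final merge must contain all leaves")

    @property
    def n(self) -> int:
        return len(self.leaves)

    @property
    def max_height(self) -> float:
        return max(m.height for m in self.merges)

    def members(self, node: int) -> tuple[int, ...]:
        """Leaf indices under an internal or leaf node id."""
        n = self.n
        if node < n:
            return (node,)
        m = self.merges[node - n]
        return tuple(sorted(self.members(m.left) + self.members(m.right)))

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n else self.merges[node - self.n].height

    def to_linkage_matrix(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix, e.g. for plotting."""
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges], dtype=float
        )


@dataclass(frozen=True)
class Partition:
    """Assignment of every point to exactly one non-empty cluster."""

    assignment: Mapping[str, object]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        if not self.assignment:
            raise ClusteringError("empty partition")

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def labels(self) -> tuple:
        """Cluster labels in first-appearance order."""
        seen: dict = {}
        for lab in self.assignment.values():
            seen.setdefault(lab, None)
        return tuple(seen)

    def clusters(self) -> dict:
        """Map cluster label -> list of member names (insertion order)."""
        out: dict = {lab: [] for lab in self.labels}
        for name, lab in self.assignment.items():
            out[lab].append(name)
        return out

    def relabelled(self, mapping: Mapping) -> "Partition":
        return Partition({name: mapping[lab] for name, lab in self.assignment.items()})

    def same_clusters(self, other: "Partition") -> bool:
        """True iff the two partitions are identical up to label permutation."""
        if set(self.assignment) != set(other.assignment):
            return False
        mine = {frozenset(v) for v in self.clusters().values()}
        theirs = {frozenset(v) for v in other.clusters().values()}
        return mine == theirs


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    """Dense Euclidean distance matrix of an (n, p) feature array."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ClusteringError("feature array must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ClusteringError("features must be finite")
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(data, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distances between countries.

    `data` is either a Dataset (single feature: the anxiety percentage) or an
    (n, p) feature array accompanied by `labels`. For a single feature the
    distance reduces to the absolute difference of percentages.
    """
    if hasattr(data, "records"):  # datasets.Dataset, duck-typed to avoid a cycle
        labels = tuple(data.countries)
        X = np.asarray(data.values, dtype=float).reshape(-1, 1)
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and labels is not None and len(labels) == X.shape[1]:
            X = X.T  # a flat vector of single-feature points
        if labels is None:
            labels = tuple(f"P{i}" for i in range(X.shape[0]))
    if X.shape[0] < 2:
        raise ClusteringError("need at least 2 points for a distance matrix")
    return DistanceMatrix(tuple(labels), pairwise_euclidean(X), features=X)


def _lw_update(linkage: str, d_ik, d_jk, d_ij, n_i, n_j, n_k):
    """Lance-Williams distance from merged cluster (i u j) to cluster k.

    For ward the inputs and output are *squared* distances.
    """
    if linkage == "ward":
        tot = n_i + n_j + n_k
        return ((n_i + n_k) * d_ik + (n_j + n_k) * d_jk - n_k * d_ij) / tot
    if linkage == "complete":
        return max(d_ik, d_jk)
    if linkage == "average":
        return (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
    if linkage == "single":
        return min(d_ik, d_jk)
    raise ClusteringError(f"unknown linkage {linkage!r}")


def agglomerate(dist: DistanceMatrix, linkage: str = "ward") -> Dendrogram:
    """Bottom-up clustering: repeatedly merge the closest pair of clusters.

    Ties on the minimal linkage distance are broken deterministically: when
    the feature coordinates are available the tied pair with the
    lexicographically smallest sorted pair of cluster centroids wins (for
    percentage data this merges the lowest-valued tied pair first and is
    invariant to record order); identical centroids, or a matrix built
    without coordinates, fall back to the smallest (min leaf index,
    max leaf index) of the pair.
    """
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = dist.n
    if n < 2:
        raise ClusteringError("need at least 2 points to agglomerate")

    # working inter-cluster distances; ward tracks squared distances
    D = dist.values.astype(float).copy()
    if linkage == "ward":
        D = D**2

    active = list(range(n))                       # current cluster node-ids
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}                # min leaf index per cluster
    if dist.features is not None:
        centroid = {i: tuple(dist.features[i]) for i in range(n)}
    else:
        centroid = None
    dd = {}                                       # (id_a, id_b) a<b -> distance
    for a in range(n):
        for b in range(a + 1, n):
            dd[(a, b)] = D[a, b]

    def _tie_key(a: int, b: int) -> tuple:
        r = (min(rep[a], rep[b]), max(rep[a], rep[b]))
        if centroid is None:
            return (r,)
        return (tuple(sorted((centroid[a], centroid[b]))), r)

    merges: list[Merge] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (dd[(min(a, b), max(a, b))], _tie_key(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d_min, _), i, j = best
        height = float(np.sqrt(d_min)) if linkage == "ward" else float(d_min)
        new_size = size[i] + size[j]
        merges.append(Merge(min(i, j), max(i, j), height, new_size))

        for k in active:
            if k in (i, j):
                continue
            d_new = _lw_update(
                linkage,
                dd[(min(i, k), max(i, k))],
                dd[(min(j, k), max(j, k))],
                d_min,
                size[i],
                size[j],
                size[k],
            )
            dd[(min(next_id, k), max(next_id, k))] = d_new
        active = [c for c in active if c not in (i, j)] + [next_id]
        size[next_id] = new_size
        rep[next_id] = min(rep[i], rep[j])
        if centroid is not None:
            ca, cb = np.array(centroid[i]), np.array(centroid[j])
            centroid[next_id] = tuple((size[i] * ca + size[j] * cb) / new_size)
        next_id += 1

    return Dendrogram(tuple(dist.labels), tuple(merges))


def _components(dendro: Dendrogram, merges: Iterable[Merge]) -> Partition:
    """Partition induced by applying a subset of the merge list."""
    n = dendro.n
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, m in enumerate(dendro.merges):
        if m in merges:
            new = n + step
            parent[find(m.left)] = new
            parent[find(m.right)] = new

    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, name in enumerate(dendro.leaves):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[name] = roots[r]
    return Partition(assignment)


def cut_to_k(dendro: Dendrogram, k: int) -> Partition:
    """Undo the last k-1 merges; connected components are the clusters."""
    n = dendro.n
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} out of range [1, {n}]")
    return _components(dendro, set(dendro.merges[: n - k]))


def cut_at_fraction(dendro: Dendrogram, fraction: float) -> Partition:
    """Cut at a horizontal line drawn at `fraction` of the maximum merge height.

    Merges whose height is strictly below threshold = fraction * max height
    are applied; everything above the line stays split. At fraction = 1.0 a
    dendrogram with a unique top merge therefore yields two clusters.
    """
    if not 0.0 < fraction <= 1.0:
        raise ClusteringError(f"fraction must be in (0, 1], got {fraction}")
    threshold = fraction * dendro.max_height
    return _components(dendro, {m for m in dendro.merges if m.height < threshold})


_NEWICK_SAFE = set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.-")


def _newick_label(name: str) -> str:
    if set(name) <= _NEWICK_SAFE:
        return name
    return "'" + name.replace("'", "''") + "'"


def _newick_node(dendro: Dendrogram, node: int, parent_height: float) -> str:
    length = parent_height - dendro.node_height(node)
    if node < dendro.n:
        return f"{_newick_label(dendro.leaves[node])}:{length:g}"
    m = dendro.merges[node - dendro.n]
    left = _newick_node(dendro, m.left, m.height)
    right = _newick_node(dendro, m.right, m.height)
    return f"({left},{right}):{length:g}"


def export_dendrogram(dendro: Dendrogram, format: str = "newick") -> str:
    """Serialize a dendrogram as Newick (branch lengths from merge heights) or JSON."""
    if format == "newick":
        m = dendro.merges[-1]
        left = _newick_node(dendro, m.left, m.height)
        right = _newick_node(dendro, m.right, m.height)
        return f"({left},{right});"
    if format == "json":
        return json.dumps(
            {
                "leaves": list(dendro.leaves),
                "merges": [
                    {"left": m.left, "right": m.right, "height": m.height, "size": m.size}
                    for m in dendro.merges
                ],
            },
            indent=2,
        )
    raise ClusteringError(f"unknown export format {format!r}")


def dendrogram_from_json(text: str) -> Dendrogram:
    obj = json.loads(text)
    merges = tuple(
        Merge(int(m["left"]), int(m["right"]), float(m["height"]), int(m["size"]))
        for m in obj["merges"]
    )
    return Dendrogram(tuple(obj["leaves"]), merges)
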