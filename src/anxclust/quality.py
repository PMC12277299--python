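"""Cluster validation: silhouette coefficient and variance-decomposition metrics.

The suite mirrors the interpretability chain used for country-percentage
clusters: the raw within-cluster sum of squares (WCSS, squared percentage
points) is divided by the number of countries to give the average square
distance, whose square root ("percentual WCSS") is back on the percentage
scale; the between-cluster sum of squares (BCSS) is reported as a total, as
an average per cluster, as the explained fraction BCSS/TSS, and as the
BCSS/WCSS ratio. WCSS + BCSS = TSS holds exactly (law of total variance).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import Dataset
from .hierarchy import (
    DistanceMatrix,
    Dendrogram,
    Partition,
    agglomerate,
    cut_at_fraction,
    cut_to_k,
    distance_matrix,
)

__all__ = [
    "ClusterQuality",
    "KSelection",
    "silhouette",
    "wcss_suite",
    "bcss_suite",
    "quality_report",
    "select_k",
]


@dataclass(frozen=True)
class ClusterQuality:
    """The full validation bundle for one partition of one dataset."""

    k: int
    n: int
    silhouette_per_point: dict[str, float]
    silhouette_mean: float
    wcss: float
    avg_square_distance: float       # wcss / n
    percentual_wcss: float           # sqrt(wcss / n), percentage points
    bcss_total: float
    avg_bcss_per_cluster: float      # bcss_total / k
    tss: float
    explained_variation: float       # bcss_total / tss, fraction in [0, 1]
    bcss_wcss_ratio: float | None    # None when wcss == 0 (all singletons)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "silhouette_mean": self.silhouette_mean,
            "silhouette_per_point": self.silhouette_per_point,
            "wcss": self.wcss,
            "avg_square_distance": self.avg_square_distance,
            "percentual_wcss": self.percentual_wcss,
            "bcss_total": self.bcss_total,
            "avg_bcss_per_cluster": self.avg_bcss_per_cluster,
            "tss": self.tss,
            "explained_variation": self.explained_variation,
            "bcss_wcss_ratio": self.bcss_wcss_ratio,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def format_table(self) -> str:
        ratio = "undefined" if self.bcss_wcss_ratio is None else f"{self.bcss_wcss_ratio:.2f}"
        rows = [
            ("clusters (k)", f"{self.k}"),
            ("countries (n)", f"{self.n}"),
            ("mean silhouette", f"{self.silhouette_mean:.2f}"),
            ("WCSS", f"{self.wcss:.2f}"),
            ("avg square distance", f"{self.avg_square_distance:.2f}"),
            ("percentual WCSS", f"{self.percentual_wcss:.2f}"),
            ("BCSS (total)", f"{self.bcss_total:.2f}"),
            ("avg BCSS per cluster", f"{self.avg_bcss_per_cluster:.2f}"),
            ("TSS", f"{self.tss:.2f}"),
            ("explained variation", f"{100 * self.explained_variation:.0f}%"),
            ("BCSS/WCSS ratio", ratio),
        ]
        width = max(len(a) for a, _ in rows)
        return "\n".join(f"{a:<{width}}  {b}" for a, b in rows)


def _cluster_indices(dist_labels, part: Partition) -> dict:
    members: dict = {lab: [] for lab in part.labels}
    index = {name: i for i, name in enumerate(dist_labels)}
    missing = set(part.assignment) ^ set(dist_labels)
    if missing:
        raise ValueError(f"partition and data disagree on countries: {sorted(missing)}")
    for name, lab in part.assignment.items():
        members[lab].append(index[name])
    return members


def silhouette(dist: DistanceMatrix, part: Partition) -> tuple[dict[str, float], float]:
    """Per-point silhouette values and their unweighted mean.

    a(i) is the mean distance from i to the other members of its own cluster,
    b(i) the minimum over other clusters of the mean distance from i to that
    cluster's members, and s(i) = (b(i) - a(i)) / max(a(i), b(i)).
    Singleton clusters get s(i) = 0 by convention. Needs k >= 2.
    """
    members = _cluster_indices(dist.labels, part)
    if len(members) < 2:
        raise ValueError("silhouette needs at least 2 clusters (b(i) is undefined for k=1)")
    D = dist.values
    per_point: dict[str, float] = {}
    for name, lab in part.assignment.items():
        i = dist.labels.index(name)
        own = [j for j in members[lab] if j != i]
        if not own:
            per_point[name] = 0.0
            continue
        a = float(np.mean(D[i, own]))
        b = min(float(np.mean(D[i, members[other]])) for other in members if other != lab)
        per_point[name] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    mean = float(np.mean([per_point[name] for name in dist.labels]))
    return per_point, mean


def _groups(data: Dataset, part: Partition) -> dict:
    members = _cluster_indices(data.countries, part)
    x = data.values
    return {lab: x[idx] for lab, idx in members.items()}


def wcss_suite(data: Dataset, part: Partition) -> tuple[float, float, float]:
    """(wcss, avg_square_distance, percentual_wcss) for a partition."""
    groups = _groups(data, part)
    wcss = float(sum(((g - g.mean()) ** 2).sum() for g in groups.values()))
    avg = wcss / data.n
    return wcss, avg, float(np.sqrt(avg))


def bcss_suite(data: Dataset, part: Partition) -> tuple[float, float, float, float | None]:
    """(bcss_total, avg_bcss_per_cluster, explained_variation, bcss_wcss_ratio).

    The ratio is None (undefined) for an all-singleton partition, where
    wcss = 0. A single-cluster partition gives bcss_total = 0.
    """
    groups = _groups(data, part)
    mu = float(data.values.mean())
    bcss = float(sum(len(g) * (g.mean() - mu) ** 2 for g in groups.values()))
    wcss, _, _ = wcss_suite(data, part)
    tss = bcss + wcss
    explained = 0.0 if tss == 0 else bcss / tss
    ratio = None if wcss == 0 else bcss / wcss
    if ratio is None and part.k > 1:
        warnings.warn("wcss is zero; BCSS/WCSS ratio is undefined", stacklevel=2)
    return bcss, bcss / part.k, explained, ratio


def quality_report(data: Dataset, part: Partition) -> ClusterQuality:
    """Assemble the full metric bundle; enforces the WCSS + BCSS = TSS identity."""
    per_point, sil_mean = silhouette(distance_matrix(data), part)
    wcss, avg_sq, pct = wcss_suite(data, part)
    bcss, avg_bcss, explained, ratio = bcss_suite(data, part)
    tss = float(((data.values - data.values.mean()) ** 2).sum())
    if not np.isclose(wcss + bcss, tss, rtol=1e-9, atol=1e-9):
        raise AssertionError(f"variance decomposition violated: {wcss} + {bcss} != {tss}")
    return ClusterQuality(
        k=part.k,
        n=data.n,
        silhouette_per_point=per_point,
        silhouette_mean=sil_mean,
        wcss=wcss,
        avg_square_distance=avg_sq,
        percentual_wcss=pct,
        bcss_total=bcss,
        avg_bcss_per_cluster=avg_bcss,
        tss=tss,
        explained_variation=explained,
        bcss_wcss_ratio=ratio,
    )


@dataclass(frozen=True)
class KSelection:
    """Outcome of the three-step cluster-count selection."""

    chosen_k: int                       # silhouette maximizer over k_range
    dendrogram_k: int                   # candidate from the fraction cut
    fraction: float
    silhouette_by_k: dict[int, float]
    quality_by_k: dict[int, ClusterQuality]
    partition: Partition                # the cut at chosen_k
    dendrogram: Dendrogram
    agree: bool


def select_k(
    data: Dataset,
    linkage: str = "ward",
    k_range: tuple[int, int] = (2, 10),
    fraction: float = 0.20,
    dendro: Dendrogram | None = None,
) -> KSelection:
    """Three sequential steps to pick the cluster count.

    1. cut the dendrogram at `fraction` of its maximum height -> candidate k;
    2. compute the mean silhouette for every k in `k_range` and record the
       maximizer (ties go to the smaller k);
    3. report the full dispersion metrics for every candidate.

    chosen_k is the silhouette maximizer; a warning is emitted when it
    disagrees with the dendrogram-cut candidate.
    """
    lo, hi = k_range
    if not 2 <= lo <= hi <= data.n - 1:
        raise ValueError(f"k_range {k_range} must lie within [2, n-1] = [2, {data.n - 1}]")
    if dendro is None:
        dendro = agglomerate(distance_matrix(data), linkage)
    dendrogram_k = cut_at_fraction(dendro, fraction).k
    quality_by_k = {k: quality_report(data, cut_to_k(dendro, k)) for k in range(lo, hi + 1)}
    sil_by_k = {k: q.silhouette_mean for k, q in quality_by_k.items()}
    chosen_k = max(sil_by_k, key=lambda k: (sil_by_k[k], -k))
    agree = chosen_k == dendrogram_k
    if not agree:
        warnings.warn(
            f"silhouette maximizer k={chosen_k} disagrees with the "
            f"{fraction:.0%} dendrogram cut (k={dendrogram_k})",
            stacklevel=2,
        )
    return KSelection(
        chosen_k=chosen_k,
        dendrogram_k=dendrogram_k,
        fraction=fraction,
        silhouette_by_k=sil_by_k,
        quality_by_k=quality_by_k,
        partition=cut_to_k(dendro, chosen_k),
        dendrogram=dendro,
        agree=agree,
    )
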