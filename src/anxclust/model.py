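"""Model/Results objects tying the clustering and comparison stages together.

`HierarchicalAnxietyModel` is built from one activity stratum's Dataset
(constructors from DataFrame, CSV, or a bundled fixture); `fit()` cuts the
dendrogram at a height fraction (the published workflow) or at a requested
k and returns a `ClusteringResults` carrying the partition, the full
validation metrics, the silhouette scan over candidate k, and a summary()
table. `PairedActivityModel` does the same for the low-vs-high Z
comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .datasets import Dataset, bundled_fixture, load_dataset, _dataset_from_frame
from .groupstats import GroupComparison, compare_all
from .hierarchy import (
    Dendrogram,
    DistanceMatrix,
    Partition,
    agglomerate,
    cut_at_fraction,
    cut_to_k,
    distance_matrix,
    export_dendrogram,
)
from .quality import ClusterQuality, KSelection, quality_report, select_k

__all__ = [
    "HierarchicalAnxietyModel",
    "ClusteringResults",
    "PairedActivityModel",
    "PairedComparisonResults",
    "round_half_up",
    "tier_clusters",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def tier_clusters(data: Dataset, part: Partition) -> dict:
    """Name clusters H-1, H-2, ... / L-1, L-2, ... by mean anxiety.

    Clusters are ordered by descending mean; those whose mean exceeds the
    grand mean are H(igh)-tier, the rest L(ow)-tier, numbered within tier.
    """
    values = dict(zip(data.countries, data.values))
    means = {lab: float(np.mean([values[c] for c in mem])) for lab, mem in part.clusters().items()}
    grand = float(data.values.mean())
    ordered = sorted(means, key=lambda lab: -means[lab])
    names: dict = {}
    h = l = 0
    for lab in ordered:
        if means[lab] > grand:
            h += 1
            names[lab] = f"H-{h}"
        else:
            l += 1
            names[lab] = f"L-{l}"
    return names


class HierarchicalAnxietyModel:
    """Agglomerative clustering of one activity stratum's country percentages.

    Parameters
    ----------
    dataset : Dataset
        Country records for one activity group; record order fixes leaf order.
    linkage : str
        'ward' (default), 'complete', 'average' or 'single'. Ward matches the
        variance-based validation metrics and is the only linkage that
        reproduces the published low-activity partition.
    """

    def __init__(self, dataset: Dataset, linkage: str = "ward") -> None:
        self.dataset = dataset
        self.linkage = linkage
        self.distance: DistanceMatrix = distance_matrix(dataset)
        self.dendrogram: Dendrogram = agglomerate(self.distance, linkage)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, group: str, linkage: str = "ward"):
        return cls(_dataset_from_frame(frame, group), linkage=linkage)

    @classmethod
    def from_csv(cls, path, group: str, linkage: str = "ward"):
        return cls(load_dataset(path, group), linkage=linkage)

    @classmethod
    def from_fixture(cls, name: str, linkage: str = "ward"):
        return cls(bundled_fixture(name), linkage=linkage)

    @property
    def endog(self) -> np.ndarray:
        return self.dataset.values

    @property
    def nobs(self) -> int:
        return self.dataset.n

    def fit(
        self,
        fraction: float = 0.20,
        k: int | None = None,
        k_range: tuple[int, int] | None = None,
    ) -> "ClusteringResults":
        """Cut the dendrogram and validate the resulting partition.

        The fitted partition comes from the `fraction` height cut unless an
        explicit `k` overrides it. The silhouette scan over `k_range`
        (default 2..min(10, n-1)) is attached as a selection diagnostic.
        """
        if k_range is None:
            k_range = (2, min(10, self.nobs - 1))
        if k is None:
            partition = cut_at_fraction(self.dendrogram, fraction)
        else:
            partition = cut_to_k(self.dendrogram, k)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # selection disagreement surfaces in summary()
            selection = select_k(
                self.dataset, self.linkage, k_range, fraction, dendro=self.dendrogram
            )
        quality = quality_report(self.dataset, partition)
        return ClusteringResults(self, partition, quality, selection, fraction)


@dataclass
class ClusteringResults:
    """Fitted partition of one activity stratum plus its validation metrics."""

    model: HierarchicalAnxietyModel
    partition: Partition
    quality: ClusterQuality
    selection: KSelection
    fraction: float

    @property
    def k(self) -> int:
        return self.partition.k

    @property
    def cluster_names(self) -> dict:
        return tier_clusters(self.model.dataset, self.partition)

    def cluster_table(self) -> pd.DataFrame:
        """One row per cluster: tier name, size, rounded mean, members."""
        data = self.model.dataset
        values = dict(zip(data.countries, data.values))
        names = self.cluster_names
        rows = []
        for lab, members in self.partition.clusters().items():
            mean = float(np.mean([values[c] for c in members]))
            rows.append(
                {
                    "cluster": names[lab],
                    "n": len(members),
                    "mean_pct": round_half_up(mean),
                    "members": "; ".join(sorted(members, key=lambda c: -values[c])),
                }
            )
        df = pd.DataFrame(rows).sort_values("mean_pct", ascending=False, kind="stable")
        return df.reset_index(drop=True)

    def membership_frame(self) -> pd.DataFrame:
        """One row per country: value and tiered cluster name."""
        data = self.model.dataset
        names = self.cluster_names
        return pd.DataFrame(
            {
                "country": data.countries,
                "anxiety_pct": data.values,
                "cluster": [names[self.partition.assignment[c]] for c in data.countries],
            }
        )

    def newick(self) -> str:
        return export_dendrogram(self.model.dendrogram, "newick")

    def dendrogram_json(self) -> str:
        return export_dendrogram(self.model.dendrogram, "json")

    def to_dict(self) -> dict:
        return {
            "anxclust_version": _pkg_version,
            "group": self.model.dataset.group_label,
            "linkage": self.model.linkage,
            "fraction": self.fraction,
            "k": self.k,
            "dendrogram_cut_k": self.selection.dendrogram_k,
            "silhouette_best_k": self.selection.chosen_k,
            "silhouette_by_k": {str(kk): v for kk, v in self.selection.silhouette_by_k.items()},
            "quality": self.quality.to_dict(),
            "clusters": {
                row.cluster: {"n": int(row.n), "mean_pct": int(row.mean_pct), "members": row.members.split("; ")}
                for row in self.cluster_table().itertuples(index=False)
            },
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def plot_dendrogram(self, ax=None, color_threshold: float | None = None):
        """Draw the dendrogram (labels = countries, y-axis = merge height)."""
        from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(12, 5))
        if color_threshold is None:
            color_threshold = self.fraction * self.model.dendrogram.max_height
        _scipy_dendrogram(
            self.model.dendrogram.to_linkage_matrix(),
            labels=list(self.model.dataset.countries),
            color_threshold=color_threshold,
            ax=ax,
        )
        ax.axhline(color_threshold, linestyle="--", color="red", linewidth=1)
        ax.set_ylabel("merge height")
        return ax

    def summary(self) -> str:
        sel = self.selection
        head = [
            "Hierarchical clustering of pre-exam anxiety percentages",
            "=" * 56,
            f"group: {self.model.dataset.group_label:<12} linkage: {self.model.linkage}",
            f"countries: {self.model.dataset.n:<8} fraction cut: {self.fraction:.0%} of max height",
            f"fitted k: {self.k:<9} dendrogram-cut k: {sel.dendrogram_k}, "
            f"silhouette-best k: {sel.chosen_k}",
        ]
        if sel.dendrogram_k != sel.chosen_k:
            head.append(
                f"note: silhouette favours k={sel.chosen_k} "
                f"(mean s = {sel.silhouette_by_k[sel.chosen_k]:.3f}); "
                f"the fraction cut gives k={sel.dendrogram_k}"
            )
        blocks = [
            "\n".join(head),
            self.quality.format_table(),
            self.cluster_table().to_string(index=False, max_colwidth=68),
        ]
        return "\n\n".join(blocks)


class PairedActivityModel:
    """Low- vs high-activity comparison across countries.

    Built from a paired table (columns country, p_low, se_low, p_high,
    se_high) or the bundled published comparison fixture.
    """

    def __init__(self, paired: pd.DataFrame) -> None:
        self.paired = paired

    @classmethod
    def from_fixture(cls, name: str = "table3_paired"):
        return cls(bundled_fixture(name))

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def fit(self) -> "PairedComparisonResults":
        comparisons, summary = compare_all(self.paired)
        return PairedComparisonResults(self, comparisons, summary)


@dataclass
class PairedComparisonResults:
    model: PairedActivityModel
    comparisons: list[GroupComparison]
    stats: dict

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.comparisons])

    def summary(self) -> str:
        df = self.frame.copy()
        for col in ("diff", "se_diff", "z"):
            df[col] = df[col].round(2)
        lines = [
            "Low- vs high-activity pre-exam anxiety comparison",
            "=" * 50,
            f"country rows: {self.stats['n_countries']}, "
            f"mean difference: {self.stats['mean_diff']:+.2f} pp (high - low)",
        ]
        agg = self.stats.get("aggregate_row")
        if agg:
            lines.append(
                f"aggregate row ({agg['country']}): diff {agg['diff']:+.2f} pp, "
                f"Z = {agg['z']:.2f} ({agg['tier']})"
            )
        return "\n".join(lines) + "\n\n" + df.to_string(index=False)
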