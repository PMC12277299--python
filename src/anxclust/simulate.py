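"""Synthetic country-level anxiety data with known cluster structure.

The generator emulates what the real analysis sees: K well-separated
clusters of country percentages in [0, 100], a per-country paired shift
between the low- and high-activity strata, and a per-country standard
error. Values are clipped (not resampled) at the [0, 100] bounds, which is
adequate for cluster means far from the boundary.

Defaults mirror the published low-activity solution: five clusters at means
41/52/60/67/78 with the published cluster sizes, within-cluster spread of
2 percentage points, a paired shift of -3 +/- 2 points (the OECD-average
change), and standard errors spanning 0.5-3.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from math import comb

import numpy as np

from .datasets import CountryRecord, Dataset
from .hierarchy import Partition

__all__ = ["SyntheticSpec", "DEFAULT_SPEC", "generate", "recovery_score"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic mixture of country percentages."""

    k: int
    cluster_means: tuple[float, ...]
    cluster_sds: tuple[float, ...]
    sizes: tuple[int, ...]
    paired_shift_mean: float = -3.0
    paired_shift_sd: float = 2.0
    se_range: tuple[float, float] = (0.5, 3.0)
    seed: int = 2018

    def __post_init__(self) -> None:
        for name in ("cluster_means", "cluster_sds", "sizes", "se_range"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("cluster_means", "cluster_sds", "sizes"):
            if len(getattr(self, name)) != self.k:
                raise ValueError(f"{name} must have length k={self.k}")
        if any(not 0 <= m <= 100 for m in self.cluster_means):
            raise ValueError("cluster_means must lie in [0, 100]")
        if any(s < 0 for s in self.cluster_sds) or self.paired_shift_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(n < 1 for n in self.sizes):
            raise ValueError("sizes must be positive")
        lo, hi = self.se_range
        if not 0 < lo <= hi:
            raise ValueError("se_range must be a pair of positive reals, lo <= hi")

    @property
    def n(self) -> int:
        return sum(self.sizes)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, obj: dict) -> "SyntheticSpec":
        return cls(**obj)


DEFAULT_SPEC = SyntheticSpec(
    k=5,
    cluster_means=(41.0, 52.0, 60.0, 67.0, 78.0),
    cluster_sds=(2.0, 2.0, 2.0, 2.0, 2.0),
    sizes=(8, 7, 16, 16, 9),
)


def generate(spec: SyntheticSpec) -> tuple[Dataset, Dataset, Partition]:
    """Draw (low-activity Dataset, high-activity Dataset, true Partition).

    Low-group values ~ Normal(cluster mean, cluster sd) clipped to [0, 100];
    high-group values add Normal(paired_shift_mean, paired_shift_sd) to the
    same country's low value; SEs are uniform on se_range. Identical seeds
    yield identical output.
    """
    rng = np.random.default_rng(spec.seed)
    names, truth, low_vals = [], {}, []
    i = 0
    for comp, (mu, sd, size) in enumerate(zip(spec.cluster_means, spec.cluster_sds, spec.sizes)):
        draws = mu + sd * rng.standard_normal(size)
        for v in draws:
            name = f"C{i:03d}"
            names.append(name)
            truth[name] = comp
            low_vals.append(v)
            i += 1
    low = np.clip(np.array(low_vals), 0.0, 100.0)
    shift = spec.paired_shift_mean + spec.paired_shift_sd * rng.standard_normal(spec.n)
    high = np.clip(low + shift, 0.0, 100.0)
    se_lo, se_hi = spec.se_range
    se_low = rng.uniform(se_lo, se_hi, spec.n)
    se_high = rng.uniform(se_lo, se_hi, spec.n)

    low_ds = Dataset(
        "low",
        tuple(CountryRecord(nm, "low", v, s) for nm, v, s in zip(names, low, se_low)),
    )
    high_ds = Dataset(
        "high",
        tuple(CountryRecord(nm, "high", v, s) for nm, v, s in zip(names, high, se_high)),
    )
    return low_ds, high_ds, Partition(truth)


def recovery_score(true: Partition, estimated: Partition) -> float:
    """Adjusted Rand index between two partitions of the same countries.

    1.0 iff the partitions are identical up to label permutation; 0 is the
    chance level; the index can go slightly negative for worse-than-chance
    agreement.
    """
    if set(true.assignment) != set(estimated.assignment):
        raise ValueError("partitions cover different country sets")
    names = sorted(true.assignment)
    t_labels = [true.assignment[nm] for nm in names]
    e_labels = [estimated.assignment[nm] for nm in names]
    n = len(names)

    # contingency table
    contingency: dict[tuple, int] = {}
    t_marg: dict[object, int] = {}
    e_marg: dict[object, int] = {}
    for t, e in zip(t_labels, e_labels):
        contingency[(t, e)] = contingency.get((t, e), 0) + 1
        t_marg[t] = t_marg.get(t, 0) + 1
        e_marg[e] = e_marg.get(e, 0) + 1

    sum_ij = sum(comb(c, 2) for c in contingency.values())
    sum_a = sum(comb(c, 2) for c in t_marg.values())
    sum_b = sum(comb(c, 2) for c in e_marg.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # degenerate: all-singletons or one cluster on both sides
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
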