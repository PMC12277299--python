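"""Two-group comparison of country anxiety percentages by activity status.

Each country contributes a low-activity and a high-activity group mean with
standard errors. The comparison statistic is the difference of means (high
minus low, so negative = anxiety lower among active students) divided by
the standard error of the difference, se_diff = sqrt(se_low^2 + se_high^2)
(independent-groups rule). |Z| is tiered against the two-sided normal
cutoffs 1.96 / 2.58 / 3.29 (p < 0.05 / 0.01 / 0.001).

A generic two-proportion Pearson chi-square is provided for the case where
raw group sizes are available; published chi-square columns without raw
sizes are treated as pass-through display values, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CountryRecord

__all__ = [
    "TIERS",
    "GroupComparison",
    "Chi2Result",
    "compare_groups",
    "compare_all",
    "chi2_two_proportions",
]

# (threshold on |z|, tier label), most stringent first
TIERS = ((3.29, "p<0.001"), (2.58, "p<0.01"), (1.96, "p<0.05"))


def significance_tier(z: float) -> str:
    for cutoff, label in TIERS:
        if abs(z) >= cutoff:
            return label
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """Low- vs high-activity comparison for one country (or aggregate row)."""

    country: str
    p_low: float
    se_low: float
    p_high: float
    se_high: float

    @property
    def diff(self) -> float:
        return self.p_high - self.p_low

    @property
    def se_diff(self) -> float:
        return float(np.hypot(self.se_low, self.se_high))

    @property
    def z(self) -> float:
        return self.diff / self.se_diff

    @property
    def tier(self) -> str:
        return significance_tier(self.z)

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "p_low": self.p_low,
            "se_low": self.se_low,
            "p_high": self.p_high,
            "se_high": self.se_high,
            "diff": self.diff,
            "se_diff": self.se_diff,
            "z": self.z,
            "tier": self.tier,
        }


def compare_groups(low: CountryRecord, high: CountryRecord) -> GroupComparison:
    """Compare one country's two activity strata; both records need an SE."""
    if low.country != high.country:
        raise ValueError(f"country mismatch: {low.country!r} vs {high.country!r}")
    if low.se is None or high.se is None:
        raise ValueError(f"{low.country}: both records need a standard error")
    return GroupComparison(low.country, low.anxiety_pct, low.se, high.anxiety_pct, high.se)


def compare_all(paired: pd.DataFrame) -> tuple[list[GroupComparison], dict]:
    """Per-row comparisons plus a cross-country summary.

    `paired` needs columns country, p_low, se_low, p_high, se_high. Rows whose
    country name contains "average" (e.g. an OECD average) are treated as
    supplied aggregates: they get a comparison like any other row but are
    excluded from the cross-country mean difference.
    """
    required = {"country", "p_low", "se_low", "p_high", "se_high"}
    missing = required - set(paired.columns)
    if missing:
        raise ValueError(f"paired table missing column(s): {sorted(missing)}")
    comparisons = [
        GroupComparison(
            str(r.country), float(r.p_low), float(r.se_low), float(r.p_high), float(r.se_high)
        )
        for r in paired.itertuples(index=False)
    ]
    countries = [c for c in comparisons if "average" not in c.country.lower()]
    aggregates = [c for c in comparisons if "average" in c.country.lower()]
    summary = {
        "n_countries": len(countries),
        "mean_diff": float(np.mean([c.diff for c in countries])) if countries else float("nan"),
        "aggregate_row": aggregates[0].to_dict() if aggregates else None,
    }
    return comparisons, summary


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    p_value: float
    low_expected_count: bool  # True when some expected cell < 1


def chi2_two_proportions(p1: float, n1: int, p2: float, n2: int) -> Chi2Result:
    """Pearson chi-square (1 df, no continuity correction) for two proportions.

    Reconstructs the 2x2 successes/failures table from the proportions and
    group sizes. Flags (rather than fails) when an expected cell drops
    below 1.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportions must be in [0, 1], got {p}")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    observed = np.array(
        [[p1 * n1, (1 - p1) * n1], [p2 * n2, (1 - p2) * n2]], dtype=float
    )
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    if np.any(expected == 0):  # both groups all-success or all-failure
        return Chi2Result(0.0, 1.0, True)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return Chi2Result(chi2, p_value, bool(np.any(expected < 1)))
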