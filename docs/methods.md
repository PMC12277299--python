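# Methods

## Data model

A dataset is one activity stratum: an ordered list of (country, anxiety
percentage, optional standard error) with the percentage in [0, 100],
unique country names, and at least two records. Record order is meaningful
— it fixes the leaf indexing of the dendrogram. The bundled fixtures
transcribe the published tables verbatim: integer percentages for the two
56-country strata, one-decimal means and SEs for the 16-row paired
comparison table. No attempt is made to reconstruct unpublished decimals;
the printed values are the only citable ground truth. The paired fixture's
χ² and p columns are carried as display-only pass-through values (the raw
per-country sample sizes needed to recompute them were never published);
several of those cells lost their decimal separator in extraction and are
stored with the separator restored (e.g. "08" → 0.08).

## Clustering

Distances are plain Euclidean; with the single anxiety feature this is the
absolute difference of percentages, in percentage points. Agglomeration is
the standard bottom-up scheme: start from singletons, repeatedly merge the
pair of clusters with minimal linkage distance, and record that distance as
the merge height. Inter-cluster distances are maintained with the
Lance–Williams recurrence; Ward runs on squared distances with the
conventional square-root scaling of heights, so exported trees are directly
comparable to mainstream implementations (the engine is merge-for-merge
identical to scipy's on tie-free data — a property the test suite checks).
The O(n³) full rescan per step is deliberate: at country scale (n = 56) it
runs in milliseconds and keeps every decision auditable.

**Tie-breaking.** Integer percentage data produces exact ties between
cluster pairs (symmetric configurations such as {61,62,63} vs {63,64,65}
at the same Ward distance). Ties are broken by the lexicographically
smallest sorted pair of cluster centroids, falling back to smallest leaf
indices only for identical centroids. This rule is invariant to record
order, merges the lowest-valued tied pair first in 1-D, and is what makes
the fitted low-activity partition land exactly on the published
five-cluster membership; an index-based tie-break would depend on the
arbitrary order countries are listed in.

**Cutting.** `cut_to_k` undoes the last k−1 merges. `cut_at_fraction`
emulates drawing a horizontal line at `fraction` of the maximum merge
height and keeps every merge *strictly below* the line; at fraction 1.0 a
tree with a unique top merge therefore yields two clusters. The default
fraction is 0.20, with 0.15 and 0.25 as the sensitivity alternates; on the
low-activity table all three give the same five clusters.

Default linkage is Ward. The choice is deliberate: the validation suite is
entirely variance-based, and Ward is the linkage whose 20% cut reproduces
the published low-activity membership (complete/average/single do not —
the suite verifies this implicitly through the fixtures). Centroid and
median linkage are excluded because their height inversions would break
the monotone-heights invariant the cut semantics rely on.

## Validation metrics

* Silhouette: a(i) = mean distance to own-cluster members, b(i) = smallest
  mean distance to another cluster, s(i) = (b−a)/max(a,b); singletons get
  s(i) = 0 (the common convention, keeping the mean defined for any k ≥ 2);
  the reported score is the unweighted mean.
* WCSS = Σ_k Σ_{i∈C_k} (x_i − μ_k)², in squared percentage points. Its
  interpretable forms: average square distance WCSS/n and "percentual
  WCSS" √(WCSS/n), back in percentage points.
* BCSS = Σ_k n_k (μ_k − μ)², with BCSS/k (average per cluster), explained
  variation BCSS/TSS (reported internally as a fraction, formatted as a
  rounded percent), and the BCSS/WCSS ratio. The ratio is undefined (None,
  with a warning) when WCSS = 0; a single-cluster partition has BCSS = 0
  by construction, not by error.
* `quality_report` asserts WCSS + BCSS = TSS to 1e−9 before returning.

**k selection** follows three sequential steps: the fraction cut proposes a
candidate k; the mean silhouette is scanned over a k range (default 2–10,
ties to the smaller k); the full dispersion metrics are attached for every
candidate. The silhouette maximizer and the dendrogram candidate frequently
disagree on real tables — on the bundled data the silhouette keeps
improving with finer partitions, while the 20% cut gives the published
counts — so the fitted partition defaults to the fraction cut and the
scan is reported as a diagnostic with an explicit disagreement note in
`summary()`.

**Cluster naming.** Clusters are ordered by descending mean; those above
the stratum grand mean are named H-1, H-2, …, the rest L-1, L-2, …
Displayed cluster means are rounded half-up to integer percent (the
high-anxiety low-activity cluster's 77.89 displays as 78); metrics are
shown at two decimals.

## Group comparison

Differences are high minus low (negative = less anxiety among active
students). The standard error of the difference uses the independent-groups
rule √(SE_low² + SE_high²) — the construction that reproduces the published
OECD-average row within rounding (Z = −5.51 vs −5.48 printed). |Z| is
tiered at 1.96 / 2.58 / 3.29 (two-sided 0.05 / 0.01 / 0.001). Several
published per-country Z entries (−43, −39, −25) are inconsistent with any
standard formula applied to the published means and SEs and are treated as
typographical; the package always recomputes Z rather than echoing them.
The two-proportion χ² reconstructs the 2×2 table from proportions and
group sizes and applies Pearson's statistic (1 df, no continuity
correction); it equals the squared pooled two-proportion z, and it flags
(rather than rejects) expected cells below 1. No survey-weighted variance
estimation and no multiple-testing correction are applied.

## Synthetic data

The generator draws K clusters of country percentages —
Normal(cluster mean, cluster SD) clipped to [0, 100] — plus a paired
low→high shift Normal(shift mean, shift SD) applied to each country's low
value, and per-country SEs uniform on a range. Clipping (not resampling)
is adequate because realistic cluster means sit far from the bounds.
Defaults mirror the published low-activity solution: five clusters at
means 41/52/60/67/78 with sizes 8/7/16/16/9, within-cluster SD 2 pp (the
spread of the published clusters), shift −3 ± 2 pp (the OECD-average
change), SEs in 0.5–3.0 (the span of the published SEs), seed 2018.

What the generator does *not* emulate: survey weighting, within-country
student-level variance, non-normal country effects, or any dependence of
the shift on the anxiety level. Passing recovery tests therefore show the
pipeline recovers planted mixture structure — they do not certify
behaviour on indicators whose noise violates these assumptions.

Partition recovery is scored with the adjusted Rand index computed from
the contingency-table definition; the degenerate case (both partitions
all-singletons or both a single identical cluster) is defined as 1.0.

## Numerical and testing choices

Problem sizes are desk-scale throughout: the real tables have n = 56, the
recovery experiment uses 100 replicates of n = 20, property tests use
n ≤ 12 with brute-force oracles and n ≤ 7 with an exhaustive rescan oracle,
so the whole suite runs in seconds. Oracle comparisons use 1e−9 absolute
or relative tolerance; the scipy/sklearn/dendropy cross-checks live only
in the test suite, never in the implementation path.

Known reproduction limits, all traceable to the printed inputs being
integer-rounded: the low-activity WCSS recomputes to 310.17 vs 309.27
published (0.3%), its mean silhouette to 0.59 vs 0.60, and its BCSS/WCSS
ratio to 22.26 vs 22.10; the high-activity metrics recompute essentially
exactly (WCSS 632.80, BCSS 7079.18, silhouette 0.56). The published
low-activity BCSS "absolute value" of 1,367.33 is the average BCSS per
cluster (total ≈ 6,903.6 ≈ 5 × 1,380.7); both are reported. The published
high-activity four-cluster *membership* is not reproducible from the
printed integers by any standard linkage (its boundaries fall at 47|49 and
57|58 where Ward on integers splits at 52|53 and 59|61) — the
corresponding acceptance test documents this and fails honestly; the
low-activity membership is reproduced exactly.
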