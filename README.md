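# anxclust

Hierarchical clustering of country-level pre-exam anxiety percentages,
stratified by adolescent physical-activity status.

## The problem

Large international school surveys report, for each country, the percentage
of 15-year-old students who say they feel anxious before exams, separately
for students with low and with high habitual physical activity. `anxclust`
groups countries with similar anxiety burdens, validates the grouping, and
asks country by country whether the physically active stratum reports less
anxiety than the inactive one. It is aimed at epidemiologists and
public-health analysts working with country-level indicator tables
(one percentage, and optionally a standard error, per country and stratum).

## Methods in brief

* **Clustering.** Agglomerative hierarchical clustering on the 1-D Euclidean
  distance d(A, B) = |x_A − x_B| between country percentages, implemented
  from scratch with the Lance–Williams recurrence (Ward, complete, average,
  single linkage). The cluster count comes from cutting the dendrogram where
  a horizontal line at 20% of the maximum merge height crosses it, with a
  silhouette scan over candidate k as a diagnostic and a 15%/25% cutoff
  sensitivity analysis.
* **Validation.** Mean silhouette s(i) = (b(i) − a(i)) / max(a(i), b(i));
  within-cluster sum of squares WCSS = Σ_k Σ_{i∈C_k} (x_i − μ_k)² with its
  interpretable forms WCSS/n and √(WCSS/n); between-cluster sum of squares
  BCSS = Σ_k n_k (μ_k − μ)² with BCSS/k, the explained variation BCSS/TSS,
  and the BCSS/WCSS ratio. WCSS + BCSS = TSS is enforced.
* **Group comparison.** Per country, Z = (p_high − p_low) / √(SE_low² + SE_high²),
  tiered at |Z| ≥ 1.96 / 2.58 / 3.29, plus a generic two-proportion Pearson
  χ² for when raw group sizes are available.
* **Synthetic data.** A generator drawing K clusters of country percentages
  with a paired low→high shift, for testing partition recovery (adjusted
  Rand index) end to end.

The published country tables this package reproduces are bundled as
fixtures (`table1_low`, `table2_high`, `table3_paired`).

## Worked example

```python
import anxclust as ax

res = ax.HierarchicalAnxietyModel.from_fixture("table1_low").fit(fraction=0.20)
print(res.summary())
```

```
Hierarchical clustering of pre-exam anxiety percentages
========================================================
group: low          linkage: ward
countries: 56       fraction cut: 20% of max height
fitted k: 5         dendrogram-cut k: 5, silhouette-best k: 10
note: silhouette favours k=10 (mean s = 0.605); the fraction cut gives k=5

clusters (k)          5
countries (n)         56
mean silhouette       0.59
WCSS                  310.17
avg square distance   5.54
percentual WCSS       2.35
BCSS (total)          6903.55
avg BCSS per cluster  1380.71
TSS                   7213.71
explained variation   96%
BCSS/WCSS ratio       22.26

cluster  n  mean_pct                                                              members
    H-1  9        78 Brazil; Dominican Republic; Colombia; Costa Rica; Malaysia; Singa...
    H-2 16        67 Australia; Uruguay; Chinese Taipei; Montenegro; Spain; Ireland; M...
    L-1 16        60 Chile; Denmark; Japan; Turkey; Hungary; Cyprus; Tunisia; China; K...
    L-2  7        52      Estonia; Israel; Lithuania; Luxembourg; France; Poland; Belgium
    L-3  8        41 Finland; Netherlands; Germany; Slovak Republic; Russia; Latvia; S...
```

The 20% cut groups the 56 low-activity countries into five clusters —
two above the grand mean (a 78% cluster led by Brazil and the Dominican
Republic and a 67% cluster) and three below (60%, 52%, and a 41% cluster
ending at the Czech Republic's 35%). The partition explains 96% of the
between-country variance (BCSS/WCSS ≈ 22), with a mean silhouette of 0.59;
√(WCSS/n) ≈ 2.35 says a typical country sits about 2.4 percentage points
from its cluster mean.

The paired comparison works the same way:

```python
cmp = ax.PairedActivityModel.from_fixture().fit()
print(cmp.summary())
# country rows: 15, mean difference: -4.78 pp (high - low)
# aggregate row (OECD average): diff -2.90 pp, Z = -5.51 (p<0.001)
```

From the shell:

```sh
anxclust run --out report/                 # cluster both strata + compare
anxclust sensitivity --fractions 0.2,0.15,0.25
anxclust simulate --seed 42 --out sim/     # synthetic data with known clusters
```

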