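# rnaconcord

Can RNA sequencing of archival tumor tissue replace immunohistochemistry
(IHC) for the clinical biomarkers that drive treatment decisions?
`rnaconcord` is the analysis pipeline for answering that question on
formalin-fixed paraffin-embedded (FFPE) cohorts: it ingests clinical
sample sheets and gene-by-sample count matrices, gates samples on
sequencing depth, normalizes and clusters expression profiles, measures
how well each biomarker gene's expression reproduces its IHC status, and
determines — by read downsampling — the minimal sequencing depth each
biomarker needs.

The package targets the four clinically actionable markers

| protein | gene (HGNC) | IHC scale | positive when |
|---------|-------------|-----------|---------------|
| HER2 | *ERBB2* | 0-3 | score = 3 ("+++") |
| ER | *ESR1* | 0-8 | score > 2 |
| PR | *PGR* | 0-8 | score > 2 |
| PD-L1 | *CD274* | 0-2 (<1%, 1-50%, >50% cells) | ≥ 1% cells stained |

but the marker panel, positivity rules and all thresholds are
configurable.

## Statistics at the core

For a marker with ordinal IHC score $s_j$ and log-normalized expression
$x_j$ across samples $j = 1..n$:

- **Spearman's rho** (tie-corrected, i.e. the Pearson correlation of
  mid-ranks) with a two-sided p-value from
  $t = \rho\sqrt{(n-2)/(1-\rho^2)}$ on $n-2$ d.f.; for $n \le 8$ the
  exact permutation p-value over all $n!$ rank orderings is used.
- **ROC AUC** from the Mann–Whitney U statistic with ties counted ½ —
  the probability that a random IHC-positive sample expresses the gene
  more highly than a random IHC-negative one.
- **Abundance percentile**: the marker's raw count ranked (mid-rank
  convention, scaled 0-100) against all genes within the same sample,
  which explains each marker's depth requirement.

Counts are normalized with the median-of-ratios estimator: gene $i$'s
geometric mean $g_i$ is taken across samples over genes with all-positive
counts, and sample $j$'s size factor is
$s_j = \mathrm{median}_i \, k_{ij}/g_i$; expression is
$\log_2(k_{ij}/s_j + 1)$. Hierarchical clustering uses the Ward
criterion applied through the Lance–Williams recurrence to unsquared
Euclidean distances (R's `hclust(method = "ward.D")`). Downsampling
draws multivariate hypergeometric subsamples of each sample's reads, so
subsampled totals hit the target depth exactly.

A synthetic-cohort generator (`rnaconcord.simulate`) produces sample
sheets and negative-binomial count matrices with IHC-score-linked marker
means, realistic marker abundance ranks, per-sample coverage variation
and RIN decaying with block age, so the whole pipeline is testable with
known ground truth. The two clinical annotation tables the defaults are
anchored to (39 breast-cancer and 19 lung-cancer FFPE samples) ship as
package data.

## Worked example

```python
from rnaconcord import SimulationConfig, marker_concordance, simulate_cohort

cohort, matrix, truth = simulate_cohort(SimulationConfig(seed=7))
for entry in marker_concordance(matrix, cohort):
    if entry.error is None:
        print(entry.protein, entry.gene, round(entry.rho, 3), round(entry.auc, 3))
```

prints:

```
HER2 ERBB2 0.824 1.0
ER ESR1 0.751 0.973
PR PGR 0.794 1.0
```

and `examples/03_marker_concordance.py`, the annotated version, expands
each line with the p-value, class sizes and abundance percentile:

```
HER2   (ERBB2): rho=0.824 p=6.4e-11 AUC=1.000 (20 pos / 20 neg)  abundance percentile 98.6 (min 95.8)
ER     (ESR1): rho=0.751 p=2.4e-08 AUC=0.973 (15 pos / 25 neg)  abundance percentile 76.5 (min 52.6)
PR     (PGR): rho=0.794 p=9.9e-10 AUC=1.000 (16 pos / 24 neg)  abundance percentile 69.9 (min 47.8)
```

Each line says: across the 40 simulated tumors, the gene's expression
ranks samples almost exactly as the pathologist's ordinal score does
(rho ≈ 0.75-0.82, all p ≪ 0.001), a positive tumor can be told from a
negative one from expression alone (AUC ≥ 0.97), and HER2 sits in the
top ~2% of all genes by raw count in every sample — which is why it
remains measurable at depths where less-expressed markers drown in
counting noise (`examples/05_coverage_saturation.py` quantifies this:
the ~10× more abundant marker reaches a stable significant correlation
at 2,000 reads per sample, the rarer one only at 10,000).

The `examples/` directory holds one short script per capability:
cohort summaries, QC correlations, marker concordance, technical
replicates, and coverage saturation. A thin CLI mirrors the same steps
(`rnaconcord simulate | normalize | qc | concordance | saturate`).

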