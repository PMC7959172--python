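# proteosect

A tested, reusable Python implementation of a comparative label-free
proteomics analysis for two-group cohorts — the kind of study that contrasts
colon adenocarcinoma (COAD) against rectal adenocarcinoma (READ) tumour
proteomes from LFQ intensity matrices. It is aimed at computational
proteomics practitioners who want the full chain — missingness handling,
differential screening, immune scoring and co-expression hub detection — as
auditable, seedable library code rather than a pile of analysis scripts.

## What it does

Given a protein × sample log2 abundance matrix with missing cells and a
two-group annotation, the pipeline runs:

1. **Missingness census and filter.** Per-protein missing counts by group;
   proteins missing in > 16 samples of *both* groups (of 20) are discarded,
   proteins missing in > 18 of one group and < 8 of the other are flagged as
   presence/absence hits, the rest are retained.
2. **Sectionalized imputation.** Missing values are split by a global
   threshold `Threshold1 = Mean_all + 2·Sd_all`: cells of low-abundance
   proteins are treated as left-censored and drawn from a down-shifted,
   shrunken per-sample Gaussian `N(Mean_s − 1.8·Sd_s, 0.3·Sd_s)`; cells of
   high-abundance proteins are treated as missing-at-random and filled by a
   distance-weighted k-nearest-neighbour rule over protein profiles. Every
   fill carries a provenance label, and an RMSE benchmark against known
   synthetic truth compares the scheme with pure-KNN and constant-fill
   baselines.
3. **Gated differential screen.** Per protein: Levene (median-centered) and
   Shapiro-Wilk gates at p > 0.1 select a pooled-variance Student t-test,
   otherwise a Mann-Whitney U test; a protein is called up/down when its
   linear fold change `2^(mean_A − mean_B)` exceeds 1.5 (or falls below
   0.67) with p < 0.05.
4. **ssGSEA immune scoring.** Per-sample gene-set enrichment via the
   integrated rank-walk statistic (exponent 0.25), additive immune scores
   over signature sets, Mann-Whitney group comparison, anti-/pro-tumor
   score correlation, z-scored infiltration matrices, and Fisher-exact
   over-representation.
5. **TOM hub detection.** Unsigned co-expression adjacency `|r|^5` over the
   differential proteins, topological overlap matrix, average-linkage cut
   into two modules, intramodular connectivity ("centrality", hub cut 30),
   PCA contribution values over the top five components, and a consensus
   hub ranking combining both.

A synthetic-data module generates cohorts with known truth (planted
effects, planted MCAR/left-censored MNAR missingness, planted correlation
blocks and hubs), so every stage is testable without any download.

## Worked example

```python
from proteosect import SyntheticSpec, run_pipeline

run_pipeline({}, "demo_run",
             synthetic_spec=SyntheticSpec(n_proteins=1000, seed=0), seed=7)
```

writes six tab-delimited tables plus `manifest.json` into `demo_run/`. With
the seeds above the manifest reports:

```
threshold1        6.3651
retained          1000
missing_totals    {'COAD': 2792, 'READ': 2812}
dep_calls         {'down': 68, 'ns': 827, 'up': 105}
n_network_nodes   173
```

Read: on the centered log2 scale the KNN/down-shift routing threshold came
out at 6.37; no protein was dropped by the missingness filter; missing
cells split almost evenly between the groups; the screen called 173 of
1,000 proteins (the generator planted 100 true up-shifts — the extra calls
are the imputation-induced false positives discussed in
`docs/methods.md`), and those 173 fed the network stage. The top of
`network_hubs.tsv`:

```
node_id  centrality  contribution  consensus_rank  module
P00122     8.211564      1.094140               1       1
P00042     8.356223      1.043134               2       1
P00966     7.874199      1.068053               3       1
```

ranks each differential protein by combined TOM centrality and PCA
contribution — on real data this consensus is what singles out a hub such
as complement component C3. `immune_comparison.tsv` holds the per-group
immune-score means and their Mann-Whitney p-value (p ≈ 0.95 here: the toy
gene sets are random, so no group difference is expected).

The same stages are exposed as CLI verbs:

```bash
proteosect simulate --n-proteins 1000 --seed 0 --outdir sim/
proteosect impute --matrix sim/matrix.tsv --annotation sim/annotation.tsv \
    --seed 7 --outdir imp/
proteosect dep --matrix imp/completed_matrix.tsv \
    --annotation sim/annotation.tsv --outdir dep/
proteosect run --simulate --seed 7 --outdir full/
```

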