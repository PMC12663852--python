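# telostrat

Tumours differ widely in how strongly they activate telomerase, the
enzyme that rebuilds chromosome ends and lets cancer cells divide
indefinitely. Given a per-sample *telomerase activity score* (an
expression-derived estimate such as an EXTEND score), a recurring
analysis pattern in pan-cancer studies is:

1. **stratify** the score vector into *low* and *high* activity groups
   with consensus k-means (k = 2) rather than an arbitrary median split;
2. **score** gene programmes (senescence/SASP, MAPK, ROS, ...) per
   sample, per cell, or per spatial spot with rank-based single-sample
   engines;
3. **compare** clinical and genomic features between the two groups with
   exact and rank tests under false-discovery-rate control;
4. **cross-tabulate** the resulting binary activity states.

`telostrat` implements this chain as a tested, reusable Python library
with a thin command-line layer, for computational biologists who have
activity scores and expression matrices in hand and want reproducible
low/high stratification plus the standard association battery around it.
Because the real cohorts behind such analyses are large controlled-access
downloads, the package also ships a **synthetic cohort generator** that
plants the statistical structure the analyses assume — a two-component
score mixture, an anti-correlated senescence programme, group-shifted
genomic-instability covariates, clinical covariates with configurable
odds ratios, and cycling/non-cycling single cells — so every stage can be
exercised end to end against known ground truth.

## Methods at a glance

**Consensus stratification.** For a score vector *x₁…xₙ*, Lloyd's
k-means (k = 2) is run in `n_iter` consensus rounds of `n_init` random
initialisations each (defaults 1000 × 50; initial centroids are distinct
observed values). Each round keeps its minimum within-cluster
sum-of-squares partition; the run-level cluster with the larger centroid
is labelled *high*; the final label is the per-sample majority vote over
rounds, with a per-sample consensus fraction and the low/high boundary
reported.

**Signature scoring.** `ssgsea_score` computes the integrated weighted
running-sum statistic ES = Σᵢ [P_in(i) − P_out(i)] over the
descending-expression gene walk, with in-set genes weighted by
rank^α (α = 0.25); `jasmine_score` averages a min–max-scaled mean-rank
component over expressed genes with an odds-ratio enrichment component
(for sparse single-cell counts); `aucell_score` is the normalised area
under the signature-recovery curve within the top-ranked fraction
(default 5 %) of genes. All three depend on the data only through
within-sample ranks.

**Association battery.** Fisher's exact test with Haldane-corrected
cross-product odds ratios for binary covariates; Welch's *t* with
Cohen's d; Wilcoxon rank-sum with the Hodges–Lehmann shift (exact
enumeration for small untied samples); Spearman correlation; and
Benjamini–Hochberg q-values computed once per submitted feature family.

## Worked example

```python
from telostrat import (SyntheticCohortConfig, simulate_cohort,
                       consensus_stratify, ssgsea_score, compare_features)

cohort = simulate_cohort(SyntheticCohortConfig(n_samples=400, seed=42),
                         include_cells=False)
strat = consensus_stratify(cohort.scores, n_iter=100, n_init=10, seed=1)
print(strat.summary())
```

```
{'n_samples': 400, 'n_low': 209, 'n_high': 191,
 'boundary': 1.2785..., 'centroids': {'low': -0.05..., 'high': 2.95...},
 'n_runs': 1000, 'n_vote_ties': 0}
```

209/400 = 52 % of samples fall in the low-activity group (the planted
share is 57 %; a handful of samples near the boundary are assigned by
score, not by their hidden label), and the boundary sits between the two
mixture components. Scoring the planted 125-gene senescence signature
and comparing it between groups:

```python
sen = ssgsea_score(cohort.expression, cohort.signature_genes).to_series()
cmp = compare_features(sen.rename("senescence").to_frame(), strat,
                       {"senescence": "welch_t"})
print(cmp[["feature_id", "effect", "q", "direction"]].to_string(index=False))
```

```
feature_id    effect             q     direction
senescence -1.375057  2.404981e-34 low_enriched
```

The senescence score is strongly enriched in the low-telomerase group
(negative high-minus-low effect), exactly the structure the generator
planted.

The same run is available from the shell:

```sh
telostrat run --out results/run1          # bundled default configuration
telostrat simulate --out cohort/ --seed 7 --cells
telostrat stratify --scores cohort/activity_scores.tsv --out strat/
telostrat score --matrix cohort/expression.tsv --gmt cohort/gene_sets.gmt \
    --method ssgsea --out senescence.tsv
```

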