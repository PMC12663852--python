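# Methods notes

## Consensus k-means stratification

The stratifier classifies a one-dimensional vector of activity scores
into *low* and *high* groups. Each consensus round draws `n_init` pairs
of distinct observed score values as initial centroids, runs Lloyd's
algorithm (nearest-centroid assignment, equivalent to a threshold at the
centroid midpoint; points exactly on the threshold join the upper
cluster) until assignments are stable, and keeps the partition with the
smallest within-cluster sum of squares — the standard multiple-restart
k-means rule. The cluster with the larger centroid is labelled *high*.
The final label is the per-sample majority vote over the `n_iter` kept
partitions; exact 0.5 ties are labelled *low* and flagged. Defaults are
`n_iter = 1000`, `n_init = 50` (50,000 Lloyd runs per vector); the test
suite and bundled configuration use reduced counts (e.g. 20 × 50 or
100 × 10), which we chose as the package's desk-scale problem sizes.

Why best-of-`n_init` rather than voting over every raw run: in 1-D the
Lloyd map has multiple fixed points whose basins can dominate random
data-point initialisation (on some vectors the global optimum is reached
by under 10 % of single runs). Voting over raw runs then converges to a
basin-size-weighted compromise rather than the optimal split, whereas
each best-of-50 round finds the global optimum with probability
≳ 1 − (1 − p)⁵⁰ and the round-level majority is then correct with
near-certainty. The package asserts this against an exhaustive
minimum-within-SS threshold-split oracle in its tests.

An alternative consensus rule (`method="coassignment"`), which
average-links the round-level co-assignment matrix and cuts it into two
groups, is provided for cross-checking; it reproduces the majority-vote
labels in ordinary practice at O(n²) cost.

Numerical notes: empty clusters cannot arise from distinct observed-value
initialisation (each initial centroid is within its own cluster); a
defensive reseed-at-farthest-point rule is implemented anyway. Labels are
invariant under positive affine transforms of the scores because
initialisation depends only on the set of distinct values and thresholds
transform linearly. Degenerate inputs (constant vectors, fewer than four
samples, fewer than two distinct values) raise errors rather than
returning arbitrary splits.

## Signature-scoring engines

All three engines consume expression only through within-sample ranks
(plus zero/non-zero status for the single-cell engine), so raw counts,
CPM, or log scales give identical scores and cross-sample normalisation
is unnecessary.

**Running-sum (bulk).** Genes are walked in descending-expression order
(ties broken stably by gene id). The enrichment score is the *sum* over
all positions of P_in − P_out, where P_in is the cumulative
rank^α-weighted in-set fraction (ascending average ranks; α = 0.25
default) and P_out the uniform ECDF of out-of-set genes. The integrated
form is a per-sample statistic with no cross-sample range normalisation —
every downstream use here is rank- or group-based, so none is needed.
Signature genes absent from the matrix are dropped with a logged warning;
an empty overlap, or a set covering every gene (empty complement), is an
error.

**Rank/odds-ratio composite (single cell).** Per cell, the rank component
is the mean ascending rank of expressed signature genes among all
expressed genes, divided by the number of expressed genes (0 if the cell
expresses no signature gene); the enrichment component is the odds ratio
of {signature, background} × {expressed, not expressed} with Haldane
+0.5 on zero cells. Each component is min–max scaled across cells
(degenerate max = min ranges map to 0 for all cells — deterministic and
test-friendly) and averaged. The odds-ratio enrichment variant is
implemented; a likelihood-ratio variant would be a straightforward
extension.

**Recovery-curve AUC (spatial/module calls).** Genes are ordered per
sample by descending expression (stable by gene id); over the top
m = ⌈τ·G⌉ positions (τ = 0.05 default) the cumulative signature-recovery
step curve is integrated and normalised by the best achievable area, so
scores lie in [0, 1] with 1 = all recoverable signature genes at the top.

## Association battery

* Fisher's exact test is two-sided (summing hypergeometric probabilities
  at most as likely as the observed table). The reported odds ratio is
  the sample cross-product ratio, Haldane-corrected when any cell is
  zero; a zero margin yields p = 1 and an undefined (NaN) odds ratio.
* Welch's t uses Satterthwaite degrees of freedom; Cohen's d uses the
  (n−1)-weighted pooled SD. Two equal constant groups return
  (t, p, d) = (0, 1, 0).
* The rank-sum p-value is exact by enumeration when the combined sample
  size is ≤ 12 with no ties, otherwise a tie-corrected normal
  approximation with continuity correction. The effect measure is the
  Hodges–Lehmann estimate (median of all pairwise between-group
  differences).
* Spearman correlation uses the t-approximation on n−2 df; constant
  inputs are flagged undefined rather than silently zero.
* Benjamini–Hochberg q-values are computed once per submitted feature
  family (one correction per comparison battery, mirroring per-analysis
  FDR reporting). Continuous effects are oriented high-minus-low, so a
  positive effect means enrichment in the high-activity group; for
  binary covariates the odds ratio is oriented toward low-group
  membership (OR > 1 = level enriched in the low group).

## Cohort-construction rules

Age schemes: *clinical* (YA 18–50 inclusive, OA > 50) and *aya*
(AYA 15–39 inclusive, OA > 39). The upper bounds are inclusive because
the schemes pair closed young ranges with strictly-greater old ranges —
the only reading with neither gap nor overlap. Under-range samples are
flagged `excluded` and removed only from age comparisons, not from
stratification. Stage strings are normalised (case, "Stage" prefix,
sub-stage letters) and collapsed to low-stage (I–II) / high-stage
(III–IV); unparsable values become `unknown` and are never silently
dropped. Mutations are *recurrent* when present in ≥ 2 cancer types;
fusions are *frequent* when present in strictly more than 1 % of a
cancer type's samples.

## Synthetic cohort generator

The generator's defaults are the package's reference study conditions:

| parameter | default | meaning |
|---|---|---|
| `mix_high` | 0.43 | planted share of high-activity samples (57 % low) |
| `mu_low`, `mu_high`, `sigma` | 0, 3, 1 | activity-score mixture components |
| `n_genes`, `signature_size` | 2000, 125 | background genes and planted senescence signature |
| `senescence_d` | 0.6 | standardised per-gene shift, low minus high |
| `coupling_rho` | −0.57 | target Spearman between activity and senescence score |
| `tmb_mean_low/high`, `tmb_dispersion` | 2.0, 3.2, 3 | negative-binomial mutation-burden means |
| `cna_mean_low/high` (concentration 20) | 0.25, 0.315 | Beta copy-number-altered fractions (≈ 0.63 standardised) |
| `loh_mean_low/high` | 0.15, 0.25 | Beta loss-of-heterozygosity fractions |
| `tl_median_low/high`, `tl_sigma` | 1.1, 0.9, 0.3 | log-normal telomere-length tumour/normal ratios |
| `clinical_or` | {sex_female: 2} | covariate odds ratio toward the low group |
| `n_cells`, `frac_cycling` | 1000, 0.4 | single-cell matrix composition |

Group sizes are deterministic (`round(mix_high·n)`) so composition
assertions are exact. All randomness flows from one root seed through a
fixed stream-splitting order (scores, expression, clinical, genomic,
cells, gene-set selection), so any generator reproduces its slice of a
full cohort when called in isolation.

**Coupling calibration.** Signature-gene values are
base_g + sd_g·(shift·1[low] + w·η_s + ε_gs) clipped at zero, with η a
shared per-sample latent normal, ε i.i.d. gene noise, and
shift = d·√(1+w²) so the realised per-gene standardised group difference
equals the planted `d` for any latent weight w. The weight w is found by
a one-dimensional root search (Brent, tolerance 0.02) on the *measured*
Spearman correlation between the regenerated activity scores and the
running-sum senescence score of the candidate matrix — the exact quantity
the target constrains — evaluated on frozen draws so the objective is
deterministic. If the target magnitude is unreachable (e.g. the undiluted
coupling is already weaker), w = 0 is used with a warning. Bases
(uniform 6–14) are large relative to per-gene SDs (uniform 0.5–2), so
zero-clipping affects ≲ 1 % of entries and is immaterial to rank-based
scoring.

The negative-binomial/Beta/log-normal distributional forms, the uniform
18–90 age range, the uniform stage dialects, and the 0.5 baseline
covariate prevalence in the high group are the generator's own choices —
plausible shapes for burden counts, genome fractions, ratios, and
covariates — not estimates of any real cohort. The generator emulates
group structure and effect sizes only: there are no library-size or GC
artefacts, batch effects, gene–gene correlation beyond the planted
programme, survival times, or spatial coordinates. Passing tests
therefore demonstrate correctness of the statistical machinery under the
planted model, not robustness to real RNA-seq artefacts.

Single-cell counts are Poisson around log-normal per-gene rates; cycling
cells (exactly `round(frac_cycling·n_cells)`) express a planted activity
programme at a fixed 3-fold elevation while non-cycling cells express the
senescence signature at (1 + `senescence_d`)-fold, so a null senescence
effect removes the single-cell contrast too.

## Pipeline and determinism

`run_pipeline` derives independent sub-seeds for simulation and
stratification from the configured seed, runs the stages in order, and
aborts with the stage name on any error. Outputs are TSV/JSON with fixed
float formatting and no timestamps, so identical configurations produce
byte-identical files. The bundled default configuration uses n = 400
samples, 2000 genes, and 100 × 10 clustering rounds.

## Known limitations

* Only k = 2 stratification is supported; multi-modal score
  distributions are collapsed to a binary state.
* The false-discovery calibration of the all-null configuration is
  reported as the mean proportion of features called at q < 0.05 across
  replicates (all such calls are false under the global null); per-family
  BH control implies this stays near the nominal level but the classical
  V/max(R,1) functional over pooled families would not be bounded by it.
* The single-cell generator plants marker contrasts without dropout
  modelling beyond Poisson sparsity.
* Survival modelling, differential expression, immune deconvolution, and
  plot rendering are intentionally out of scope; the cross-tabulation
  behind state-flow diagrams is emitted as a table.
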