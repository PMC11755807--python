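# piwiflow

Analysis toolkit for the **transposable-element (TE) / piRNA axis** in
myelodysplastic neoplasms (MDS) and similar cohort designs. It is aimed at
computational biologists who study parallel RNA-seq (TEs + protein-coding
genes) and small RNA-seq (piRNAs) profiles of patient cohorts and want a
tested, reproducible implementation of the full analysis chain — from raw
small-RNA reads to survival models and co-expression modules — together
with a synthetic cohort generator that makes every stage verifiable
without patient data.

## What it computes

piRNAs silence TEs through PIWI-clade Argonaute proteins; in higher-risk
MDS, TE expression falls while piRNA levels (and *PIWIL2*) rise, and the
coordinated shift carries prognostic information. The package implements:

* **piRNA quantification** (`piwiflow.pirnaquant`) — adapter trimming with
  UMI extraction, a 24–34 nt insert filter, *exact* full-length matching to
  a piRNA reference (no mismatches, no length tolerance, no reverse
  complement), and UMI deduplication with the directional network rule
  (edge `a → b` iff Hamming(a, b) = 1 and `count(a) ≥ 2·count(b) − 1`).
  Counts are keyed by unique sequence, so duplicate database entries never
  multi-count a molecule.
* **Normalization + differential expression** (`piwiflow.normdea`) —
  median-of-ratios size factors
  `s_j = median_i( k_ij / (∏_v k_iv)^(1/n) )` and a two-group negative
  binomial Wald test: per-feature group means on the normalized scale, a
  pooled method-of-moments dispersion `α` with `Var = μ + αμ²`, log2 fold
  change with pseudocount 0.5, and Benjamini–Hochberg FDR.
* **Totals, ratio and cutoffs** (`piwiflow.aggstats`) — per-sample total
  normalized TE and piRNA levels, the **TE:piRNA ratio** (low ratio = TE
  suppression with piRNA elevation), TE class composition, Pearson
  correlation, Welch t / Welch ANOVA, and control-extremum dichotomization
  (cutoff = control minimum for TE-like statistics, control maximum for
  piRNA-like ones; boundary values fall on the control-like side).
* **Survival** (`piwiflow.survival`) — Kaplan–Meier product-limit curves,
  the log-rank test, a Newton–Raphson Cox proportional-hazards fit
  (Breslow ties, Efron optional) with Wald CIs from the observed
  information, IPSS-R ordinal coding of clinical covariates, and
  forward-stepwise selection with backward elimination
  (`p_enter = 0.05`, `p_remove = 0.10`).
* **Correlation-network modules** (`piwiflow.netmod`) — a complete Pearson
  graph over log2(x+1) normalized PCG+TE+piRNA panels; a seed module is the
  seed, its top-k neighbors by |r| and their top-k neighbors, edge-filtered
  at the third quartile of |r| over all member pairs; export to
  GraphML/SIF for Cytoscape.
* **Enrichment** (`piwiflow.enrich`) — preranked GSEA (weighted
  Kolmogorov–Smirnov running sum, gene-label permutations, NES, add-one
  permutation p, sign-stratified FDR) and hypergeometric
  over-representation with BH FDR.
* **Synthetic cohorts** (`piwiflow.synthcohort`) — NB count matrices with
  group shifts and a latent bivariate per-sample factor pair, clinical and
  survival tables, and FASTQ-level read simulation with PCR duplication,
  all with recorded ground truth.

`piwiflow.pipeline.run_all` chains the stages from one YAML config and
writes a run manifest; the `piwiflow` CLI exposes the verbs
`simulate`, `quantify`, `dea`, `aggstats`, `survive`, `network`, `enrich`
and `all`.

## Worked example

```python
from piwiflow import (CohortConfig, generate_cohort, size_factors, normalize,
                      totals, control_cutoff, pearson, logrank)

cohort = generate_cohort(CohortConfig(seed=1))          # 17 CTR / 45 LR / 35 HR
norm_te = normalize(cohort.te_counts, size_factors(cohort.rna_library()))
norm_pi = normalize(cohort.pirna_counts, size_factors(cohort.small_library()))
tot = totals(norm_te, norm_pi, groups=cohort.clinical["group"])

r, p = pearson(tot["total_te"], tot["total_pirna"])
rule = control_cutoff(tot["ratio"], cohort.clinical["group"] == "CTR",
                      "control-minimum", "ratio")
strata = rule.assign(tot["ratio"])
srec = cohort.survival.query("endpoint == 'OS'").set_index("sample")
chi2, p_lr = logrank(srec["time"], srec["event"], strata.loc[srec.index])
print(f"r = {r:.3f} (p = {p:.2g}); ratio cutoff = {rule.cutoff:.3f}; "
      f"log-rank p = {p_lr:.2g}")
```

prints

```
r = -0.648 (p = 7.4e-13); ratio cutoff = 0.533; log-rank p = 6.8e-07
```

i.e. samples with suppressed TEs carry elevated piRNA levels (negative
correlation of the totals), and MDS patients whose TE:piRNA ratio falls
below anything observed in controls have significantly worse overall
survival. The scripts in `examples/` walk through each capability in the
same style (simulation, quantification, DEA, totals/ratio, survival,
network modules, enrichment) and print a line of interpretation with each
number.

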