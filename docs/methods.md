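# Methods

This note documents the statistical models behind piwiflow, the defaults
and why they were chosen, what the synthetic cohort emulates (and does
not), and the numerical conventions that matter for reproducibility.

## The synthetic cohort model

`generate_cohort` draws a three-group cohort — healthy controls (CTR),
lower-risk (LR-MDS) and higher-risk (HR-MDS) patients, by default
17/45/35 samples — with four count blocks: TEs (687), piRNAs (257),
protein-coding genes (1500, including *PIWIL2* and *PIWIL4*) and a
miRNA-like small-RNA background (300).

**Counts.** Feature *i* in sample *j* is negative binomial with mean
`μ_ij = b_i · 2^(δ_i g_j + u_j) · d_j` and variance `μ + αμ²`
(dispersion `α = 0.2` by default; `α = 0` falls back to Poisson).
Baselines `b_i` are log-normal (log2 means 6–8, SD 1.5). The group shift
`δ` is `te_hr_logfc = −1` for every TE and `pirna_hr_logfc = +1` for every
piRNA in HR-MDS samples, zero elsewhere. `d_j` is a per-library sequencing
depth (`2^N(0, 0.25)`), drawn separately for the RNA-seq and small RNA-seq
libraries.

**Latent coupling.** Each sample carries a latent factor pair
`(u_te, u_pi) ~ N(0, 0.5² · [[1, ρ], [ρ, 1]])` with `latent_rho = −0.4`:
`u_te` scales all TE features, `u_pi` all piRNA features. The coupling is
modelled at the per-sample total level — one factor per molecule class —
because the biological claim being emulated concerns total TE vs total
piRNA levels, not feature-level pairs. *PIWIL2*'s latent log2 expression
adds `piwil2_coupling · u_pi` (coefficient 1.0), so its normalized
expression tracks the total piRNA level.

**Why the miRNA background exists.** A shift applied to *every* feature of
a library is a per-sample column scaling and is removed exactly by
median-of-ratios normalization — a piRNA-only small-RNA matrix would make
the configured piRNA elevation (and the latent factors) unobservable
downstream. Real libraries do not have this degeneracy because each
contains a stable majority: protein-coding genes in RNA-seq, miRNAs in
small RNA-seq. The generator reproduces that structure: size factors are
estimated per *library* (`Cohort.rna_library()` = PCG + TE;
`Cohort.small_library()` = piRNA + miRNA background), anchored by the
unshifted majority, and the TE/piRNA shifts survive normalization the way
they do in real data. A consequence worth knowing: because ~31% of the
RNA library (the TEs) shifts in HR-MDS, the size factors absorb part of
that shift and a mild composition bias leaks into the PCG stratum — the
same bias any median-of-ratios analysis of globally shifted data shows.

**Clinical covariates and survival.** Age ~ N(70, 10²), sex ~ 45% female,
hemoglobin/platelets/neutrophils from group-shifted (log-)normal
distributions, marrow blasts enriched above 5% in HR-MDS, cytogenetic risk
an ordered 0–4 code with worse categories more frequent in HR-MDS. OS and
PFS times are exponential with
`log h = log(baseline_hazard) + hr_group_loghr·1[HR] + 0.03·(age − 70)
+ 0.6·(u_pi − u_te)`,
i.e. a constant baseline hazard (0.02 events/month), an HR-group log
hazard ratio of 1.1, and a latent term that makes a low TE:piRNA ratio
prognostic beyond group membership. Censoring is independent uniform on
(0, 72] months; PFS hazards are 1.4× OS hazards. The exponential form was
chosen so recovery tests have closed-form truth; it does not emulate the
shape of real survival curves, only their ordering.

**What passing tests show — and don't.** The generator reproduces the
cohort's *statistical* structure (effect directions, a latent correlation,
proportional hazards), not real data: no batch effects, no mutation or
karyotype structure, no piRNA sequence families beyond a small duplicated
fraction (2% of identifiers reuse an earlier sequence), no length/GC
biases in reads, and variance parameters chosen for test power rather than
fidelity (no published per-group variances exist to match). Recovery of an
effect here demonstrates correctness of the estimators, not performance on
real cohorts.

## piRNA quantification

Reads follow the layout `insert + 3' adapter + UMI (+ padding)` with
default adapter `AACTGTAGGCACCATCAAT` and a 12-nt UMI, reflecting a
QIAseq-style small-RNA kit; both are parameters because kits differ.
Stages: (1) leftmost exact adapter occurrence; failures are flagged, not
raised; (2) inclusive 24–34 nt insert filter — wider than the canonical
26–31 nt piRNA range, deliberately, to keep boundary-length molecules;
(3) exact full-length match to the reference after U→T normalization;
reads containing `N` never match and reverse complements are not
considered (stranded protocol); (4) UMI deduplication with the directional
network rule (`a → b` iff Hamming = 1 and `count(a) ≥ 2·count(b) − 1`),
cluster roots claimed in descending count order with ties broken
lexicographically; a `unique` mode (distinct UMIs) is available.

Counts are keyed by unique sequence. piRNA databases contain many
identifiers sharing one sequence; counting per identifier would multiply
one molecule across entries. Each sequence reports all identifiers and the
lexicographically smallest as representative.

## Differential expression surrogate

The DEA stage is a transparent two-group NB Wald test, not a DESeq2
reimplementation: no dispersion shrinkage, no independent filtering, no
outlier replacement. Choices that matter:

* size factors: median of `k_ij / geomean_i` over features with all
  positive counts; an error is raised if none exists;
* dispersion: method-of-moments `α = (s² − m)/m²` per group, pooled by
  residual df, floored at 1e-8 to avoid degenerate Wald SEs;
* log2FC: `log2((m₂ + 0.5)/(m₁ + 0.5))` on the normalized scale — the
  pseudocount stabilizes low-count features;
* Wald statistic: natural-log fold change over a delta-method SE from
  `Var = μ + αμ²`; two-sided p from a **t reference with n₁ + n₂ − 2 df**.
  The t reference is deliberate: the moment dispersion estimate is itself
  noisy at cohort-scale group sizes, and a plain normal reference is
  measurably anticonservative (null rejection ~0.067 at n = 10 vs 10
  instead of 0.05); the t tail absorbs the SE noise and restores nominal
  calibration (~0.050);
* FDR: Benjamini–Hochberg; significance calls use strict `FDR < cutoff`
  and are partitioned by log2FC sign.

Exact numerical concordance with DESeq2 is not claimed anywhere.

## Totals, ratio and control cutoffs

Totals are sums of *normalized* counts per sample; raw-count totals exist
behind a flag for sensitivity analysis only. The TE:piRNA ratio is
undefined (NaN + flag) when the piRNA total is zero. Cutoffs derive from
the control group alone: control minimum for TE-like statistics ("low"
strictly below), control maximum for piRNA-like ones ("high" strictly
above); boundary values are assigned to the control-like side, a
convention that had to be fixed somewhere and is tested. No cross-library
renormalization beyond per-library size factors is attempted — the two
totals come from different libraries and only their per-sample pairing is
interpreted. Welch's ANOVA uses the classical Welch (1951) statistic with
the Welch–Satterthwaite denominator df; with k = 2 it reduces to the
squared Welch t.

## Survival modelling

Kaplan–Meier is the standard product-limit estimator; the median is the
smallest observed time with `S(t) ≤ 0.5` and undefined when never reached.
The log-rank statistic sums observed-minus-expected events over event
times with the hypergeometric variance. The Cox fit maximizes the Breslow
partial likelihood (Efron available) by Newton–Raphson with step-halving,
tolerance 1e-8 on the coefficient change, at most 50 iterations; SEs come
from the inverse observed information, CIs as `exp(β ± 1.96·SE)`.
Divergence (|β| > 50) is reported as monotone likelihood naming the
covariate. On tie-free data the score test at β = 0 equals the log-rank
statistic (classical equivalence, verified to 1e-6), and KM-figure hazard
ratios are computed from a univariate Cox fit on the binary stratum.

IPSS-R ordinal codes: hemoglobin (g/dL) <8→2, 8–<10→1, ≥10→0; platelets
(×10⁹/L) <50→2, 50–<100→1, ≥100→0; neutrophils (×10⁹/L) <0.8→1, ≥0.8→0;
blasts (%) ≤2→0, >2–<5→1, 5–10→2, >10→3; the cytogenetic category passes
through as its ordered 0–4 code. Age enters multivariate models
untransformed (per-year hazard ratio); sex as female = 1.

Stepwise selection is forward with backward checks: add the candidate with
the smallest Wald p below `p_enter = 0.05` (ties broken by candidate
order), then repeatedly drop the worst included covariate above
`p_remove = 0.10`; candidates whose trial fit fails (constant, collinear,
diverging) are skipped, and an empty final model is a legal outcome. One
calibration fact worth stating: with `p_enter = 0.05` the probability that
a pure-noise panel stays empty is ≈ 0.95^k for k candidates, so large
noise panels *will* admit a covariate occasionally — the pure-noise
recovery test uses a 3-candidate panel (expected empty rate ≈ 86%), which
is the regime where "usually empty" is actually achievable.

## Network modules

Edges carry the Pearson r of log2(x+1) normalized values (Spearman by
flag). "Most strongly correlated neighbors" is top-k by |r| with default
k = 10, ties broken by ascending identifier so extraction is deterministic
and row-order invariant. The Q3 filter threshold is the type-7
(linear-interpolation) third quartile of |r| over *all* unordered member
pairs — the complete graph on the module, not just the extraction edges —
and retention is strictly `|r| > Q3`; a signed-r variant exists for
sensitivity checks. The quantile convention is stated because Q3
definitions differ across software. The pipeline caps the complete-graph
panel at the 300 most variable molecules plus the requested seeds, since
the graph is quadratic in panel size.

## Enrichment

GSEA: genes ranked by a signed statistic (descending, ties broken by
identifier); hits increment the running sum by `|s|^p / Σ|s|^p` (default
weight p = 1), misses decrement by `1/(N − N_hit)`; ES is the signed
extremum. Significance uses **gene-label permutations** (set membership
reassigned to random rank positions) rather than phenotype permutations —
re-fitting the DEA inside the permutation loop is out of scope at this
scale, and the divergence is stated rather than hidden. NES divides ES by
the mean |null ES| of matching sign; p is the add-one same-sign tail
fraction (hence ≥ 1/(n_perm + 1)); FDR follows the sign-stratified
NES-comparison convention, capped at 1. The default ranking metric is the
DEA Wald statistic. ORA is the upper-tail hypergeometric
`P(X ≥ k)` given universe, in-universe set size and module size, with BH
across sets; the default universe is all tested PCGs.

## Pipeline problem sizes

The orchestrated run uses the default cohort (97 samples, 687/257/1500/300
features), validates quantification at read level on one sample
down-sampled to 4000 molecules (multinomial thinning; read simulation is
linear in molecule count and the validation needs coverage, not census),
uses 500 permutations for GSEA and a 300-molecule network panel. These are
the package's working defaults; every one is a config field.

## Known limitations

* The NB Wald surrogate trades DESeq2's shrinkage machinery for
  transparency; low-count features have noisier fold changes.
* Exponential survival and uniform censoring are analytic conveniences.
* Gene-label GSEA permutations ignore inter-gene correlation, which makes
  enrichment p-values optimistic on strongly co-expressed blocks.
* The control-extremum cutoff is sensitive to control outliers by
  construction (it is the study design being implemented, not a robust
  estimator).
* Proportional-hazards diagnostics, time-dependent covariates and
  competing risks are out of scope.
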