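"""Total TE / piRNA levels, the TE:piRNA ratio and control-derived cutoffs.

Per-sample totals are sums of normalized counts; the TE:piRNA ratio (low =
TE suppression with piRNA elevation) is dichotomized at the minimum ratio
observed in the control group, so "low ratio" means below anything seen in
a healthy donor.
"""

from piwiflow import (
    CohortConfig, generate_cohort, size_factors, normalize,
    totals, composition, control_cutoff, pearson, welch_t,
)

cohort = generate_cohort(CohortConfig(seed=1))
clin = cohort.clinical

norm_te = normalize(cohort.te_counts, size_factors(cohort.rna_library()))
norm_pi = normalize(cohort.pirna_counts, size_factors(cohort.small_library()))
tot = totals(norm_te, norm_pi, groups=clin["group"])

frac, mean_frac = composition(norm_te, cohort.te_counts.annotations["class"])
print("mean TE class composition:",
      {k: round(v, 3) for k, v in mean_frac.items()})

r, p = pearson(tot["total_te"], tot["total_pirna"])
print(f"\nPearson r(total TE, total piRNA) = {r:.3f} (p = {p:.2g})")
print("(a negative correlation: samples with suppressed TEs carry more piRNA)")

lr = tot[clin["group"] == "LR-MDS"]
hr = tot[clin["group"] == "HR-MDS"]
for stat in ("total_te", "total_pirna", "ratio"):
    t, p = welch_t(lr[stat], hr[stat])
    print(f"Welch t LR vs HR, {stat:>12}: t = {t:+.2f}, p = {p:.2g}")

rule = control_cutoff(tot["ratio"], clin["group"] == "CTR", "control-minimum", "ratio")
strata = rule.assign(tot["ratio"])
counts = strata[clin["group"] != "CTR"].value_counts()
print(f"\nratio cutoff (control minimum) = {rule.cutoff:.3f}")
print(f"MDS patients below it ('low ratio'): {counts.get('low', 0)}, "
      f"at or above ('high ratio'): {counts.get('high', 0)}")
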