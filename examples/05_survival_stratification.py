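"""Survival stratified by the TE:piRNA ratio, plus multivariate Cox.

Kaplan-Meier curves and the log-rank test compare MDS patients below vs
at/above the control-minimum ratio cutoff; the multivariate model combines
IPSS-R ordinal clinical codes with age, sex and the expression strata and
keeps only independent predictors via forward-stepwise selection.
"""

import pandas as pd

from piwiflow import (
    CohortConfig, generate_cohort, size_factors, normalize, totals,
    control_cutoff, km_curve, logrank, cox_fit, ipssr_ordinalize, stepwise_cox,
)

cohort = generate_cohort(CohortConfig(seed=1))
clin = cohort.clinical

norm_te = normalize(cohort.te_counts, size_factors(cohort.rna_library()))
norm_pi = normalize(cohort.pirna_counts, size_factors(cohort.small_library()))
tot = totals(norm_te, norm_pi)
rule = control_cutoff(tot["ratio"], clin["group"] == "CTR", "control-minimum", "ratio")
strata = rule.assign(tot["ratio"])

srec = cohort.survival.query("endpoint == 'OS'").set_index("sample")
strata = strata.loc[srec.index]

for level in ("low", "high"):
    sub = srec[strata == level]
    km = km_curve(sub["time"], sub["event"])
    med = "not reached" if km.median != km.median else f"{km.median:.1f} months"
    print(f"{level}-ratio group: n = {len(sub)}, median OS = {med}")

chi2, p = logrank(srec["time"], srec["event"], strata)
uni = cox_fit(srec["time"].to_numpy(), srec["event"].to_numpy(),
              pd.DataFrame({"low_ratio": (strata == "low").astype(float)}))
lo, hi = uni.ci
print(f"\nlog-rank: chi2 = {chi2:.2f}, p = {p:.2g}")
print(f"univariate Cox HR (low vs high ratio) = {uni.hr[0]:.2f} "
      f"[95% CI {lo[0]:.2f}-{hi[0]:.2f}]")

cand = ipssr_ordinalize(clin.loc[srec.index]).astype(float)
cand["age"] = clin.loc[srec.index, "age"]
cand["female_sex"] = (clin.loc[srec.index, "sex"] == "F").astype(float)
cand["ratio_low"] = (strata == "low").astype(float)
model = stepwise_cox(srec["time"].to_numpy(), srec["event"].to_numpy(), cand)
print("\nstepwise multivariate Cox (OS) retained:")
print(model.summary().round(4).to_string() if model.names else "  (empty model)")
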