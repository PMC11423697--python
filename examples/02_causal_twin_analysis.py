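"""Causal and twin-design analyses of a screened CpG.

Estimates the 5-year average causal exposure-effect risk ratio (high vs low
methylation) by G-computation on the Fine-Gray model, the within-pair
intraclass correlations by zygosity (the MZ ICC upper-bounds heritability),
and the matched case-cotwin stratified Cox fit that cancels confounding
shared within a pair.
"""

import numpy as np

from twinsurv import (
    CohortConfig,
    ate_risk_ratio,
    dichotomize,
    generate_cohort,
    icc_by_zygosity,
    impute_missing,
    matched_pair_analysis,
    residualize,
)

cfg = CohortConfig(
    n_pairs=400, n_cpgs=30, n_causal=1, causal_log_shr=(np.log(2.5),),
    base_rate_cause1=0.01, seed=7,
)
cohort, methylation, outcomes, truth = generate_cohort(cfg)
residuals = residualize(impute_missing(methylation, cohort), cohort)
cpg = truth["cpg_id"].iloc[0]

exposure = dichotomize(residuals)[cpg]
ate = ate_risk_ratio(
    exposure.to_numpy(), outcomes, cohort["pair_id"].to_numpy(),
    horizon=5.0, n_boot=200, seed=1, cpg_id=cpg,
)
print(f"{cpg}: 5-year risk {ate.risk_high:.4f} (high methylation) vs "
      f"{ate.risk_low:.4f} (low)")
print(f"ATE risk ratio {ate.ate_ratio:.2f} "
      f"(95% CI {ate.ci_lower:.2f}-{ate.ci_upper:.2f}, p={ate.p_value:.2g})")
print("a ratio above 1 says forcing everyone to high methylation would raise "
      "the 5-year cumulative incidence relative to forcing everyone low\n")

icc = icc_by_zygosity(residuals, cohort, [cpg])[0]
print(f"ICC MZ {icc.icc_mz:.2f} {icc.icc_mz_ci}, "
      f"DZ {icc.icc_dz:.2f} {icc.icc_dz_ci}")
print(f"heritability upper bound (MZ ICC): {icc.heritability_upper_bound:.2f}\n")

matched = matched_pair_analysis(residuals[[cpg]], outcomes, cohort)
print("matched (pair-stratified) fit:")
print(matched.to_string())
print("agreement between the matched and unmatched hazard ratios argues "
      "against confounding by factors shared within twin pairs")
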