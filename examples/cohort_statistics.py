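"""Cohort statistics on a synthetic per-eye table.

Draws a 32-eye diseased / 30-eye control cohort calibrated to the studied
population, then runs the full statistics stage: group comparison
(Mann-Whitney), density-covariate correlations (Pearson), and the
univariate -> multivariate logistic screen for anti-VEGF treatment response.
"""

from uwfchoroid import SyntheticCohortSpec, generate_cohort
from uwfchoroid.pipeline import run_cohort

cohort = generate_cohort(SyntheticCohortSpec(seed=11))
report = run_cohort(cohort)

comp = report["comparison"].loc[["cvd_total", "sfct_um", "haller_um"]]
print("Group comparison (PCV vs control), mean +/- SD and Mann-Whitney p:")
print(comp.round(3).to_string())
print()
corr = report["correlation"].loc[["cmt_um", "sfct_um", "haller_um"], ["R_cvd_total", "p_cvd_total"]]
print("Correlation of total choroidal vascular density with thickness measures:")
print(corr.round(3).to_string())
print()
print("Responder analysis (univariate logistic, poor response = positive):")
print(report["responder_univariate"].round(3).to_string())
print()
print("A p below 0.05 for cvd_total in the comparison row means the diseased")
print("group's higher choroidal density is detected at this sample size; the")
print("positive correlations echo the choroidal congestion interpretation.")
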