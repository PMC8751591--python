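"""Time-dependent ROC, optimal cutoff, Kaplan-Meier stratification.

Evaluates a fitted risk score at the 1/3/5-year horizons, finds the
Youden-optimal cutoff on the 1-year curve, splits patients into
high/low risk and compares their survival with the log-rank test and
Cox models over score + clinical covariates.
"""

import warnings

from irlpair import PipelineConfig, SimConfig, generate_cohort
from irlpair.pipeline import run_on_cohort

warnings.filterwarnings("ignore")

cohort = generate_cohort(SimConfig(seed=1))
result = run_on_cohort(cohort, PipelineConfig(n_cycles=200, min_freq=20, seed=1))

for horizon, roc in result.rocs.items():
    print(f"AUC at {horizon:>4d} days : {roc.auc:.3f} "
          f"({roc.n_cases} cases / {roc.n_controls} controls)")

cut = result.cutoff
print(f"\noptimal 1-year cutoff : {cut.cutoff:.3f} "
      f"(sens {cut.sensitivity:.2f}, spec {cut.specificity:.2f})")
print(f"high / low risk       : {(result.groups == 'high').sum()} / "
      f"{(result.groups == 'low').sum()}")
chi2, p = result.logrank
print(f"log-rank              : chi2 = {chi2:.1f}, p = {p:.2e}")

uni, multi = result.clinical_cox
print("\nmultivariate Cox over score + clinical covariates (HR, p):")
print(multi[["hr", "p_value"]].round(4))
# the risk score should stay significant next to grade/stage, which are
# themselves noisy readouts of the same underlying risk
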