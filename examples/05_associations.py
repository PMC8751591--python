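"""Downstream correlates: clinical, infiltration, checkpoint, drugs.

The generator plants known directions (NK cells and regulatory T cells
positively correlated with risk, neutrophils negatively; CTLA4 up and
CD274 down in high-risk tumors; lower sunitinib IC50 in the high-risk
group), so every table below has a known right answer.
"""

import warnings

from irlpair import PipelineConfig, SimConfig, generate_cohort
from irlpair.pipeline import run_on_cohort

warnings.filterwarnings("ignore")

cohort = generate_cohort(SimConfig(seed=1))
result = run_on_cohort(cohort, PipelineConfig(n_cycles=200, min_freq=20, seed=1))

print("risk group vs clinical covariates (chi-square):")
print(result.clinical_assoc[["statistic", "p_value"]].round(4))

print("\ninfiltration columns retained at p < 0.05 (Pearson r with score):")
corr = result.infiltration_corr
print(corr[corr["retained"]][["r", "p_value", "fdr"]].round(4))

print("\ncheckpoint genes (Wilcoxon high vs low; estimate = median shift):")
print(result.checkpoint_tests[["p_value", "estimate"]].round(4))

print("\ndrug IC50 (negative estimate = more sensitive when high-risk):")
print(result.drug_tests[["p_value", "estimate", "note"]].round(4))
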