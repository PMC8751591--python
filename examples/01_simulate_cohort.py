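"""Generate a synthetic ccRCC-like cohort with planted prognostic pairs.

The generator plants three lncRNA pairs whose binary indicators drive
an exponential proportional-hazards model, plus co-expression with
immune genes, differential expression, correlated clinical covariates,
and infiltration/IC50 columns with known directions.
"""

from irlpair import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(seed=1))

print(f"expression matrix : {cohort.expression.values.shape[0]} genes x "
      f"{cohort.expression.values.shape[1]} samples")
print(f"tumor / normal    : {len(cohort.expression.samples_in_group('tumor'))} / "
      f"{len(cohort.expression.samples_in_group('normal'))}")
print(f"event rate        : {cohort.survival.data['event'].mean():.2f} "
      "(1 - censoring fraction)")
print(f"planted pairs     : {cohort.truth.planted_pair_ids}")
print(f"planted log-HR    : {cohort.truth.planted_pairs[0][2]}")

# The planted truth is what recovery studies score against: the pipeline
# should rediscover these pairs from the expression + survival data alone.
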