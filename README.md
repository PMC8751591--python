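# irlpair

Rank-based immune-related lncRNA **pair** signatures for cancer
prognosis, implemented as a tested, reusable Python pipeline and
exercised end-to-end on synthetic cohorts with planted effects.

## The problem

Expression-level prognostic signatures break when data move across
platforms or normalisation schemes. A pair signature sidesteps this:
for each pair of long non-coding RNAs (A, B) and sample *s* it records
only the binary indicator

```
alpha_s(A, B) = 1  if  x_A(s) > x_B(s),  else 0
```

which depends on the within-sample *ordering* of two genes, never on
their magnitudes. `irlpair` implements the full workflow built on that
primitive for clear cell renal cell carcinoma (ccRCC):

1. screen lncRNAs co-expressed with immune genes (Pearson r > 0.4,
   p < 0.001);
2. keep differentially expressed ones (|log2 FC| > 1.5, FDR < 0.05,
   Wilcoxon + Benjamini–Hochberg);
3. encode all gene pairs and keep *effective matches* (indicator
   one-fraction strictly inside 0.2–0.8);
4. select prognostic pairs: univariate Cox screen (p < 0.01) →
   bootstrap-resampled cross-validated LASSO-Cox selection frequency
   (1000 cycles, keep > 100) → multivariate Cox (keep p < 0.05);
5. score patients with `score = Σ coef_i · alpha_i`, evaluate with
   time-dependent ROC at 1/3/5 years, a Youden-optimal cutoff,
   Kaplan–Meier / log-rank stratification, and independent-predictor
   Cox models;
6. test downstream correlates: clinical covariates (chi-square,
   Wilcoxon/Kruskal), immune-infiltration scores (Pearson), checkpoint
   genes and drug IC50 values (Wilcoxon).

A synthetic-cohort generator (`irlpair.datagen`) plants known pairs,
effect directions and clinical structure, so every stage is testable
without external downloads. See `docs/methods.md` for the model,
estimator choices and the generator's assumptions.

## Worked example

```python
from irlpair import SimConfig, PipelineConfig, generate_cohort, planted_recovery_report
from irlpair.pipeline import run_on_cohort

cohort = generate_cohort(SimConfig(seed=1))           # 400 tumor / 50 normal
result = run_on_cohort(cohort, PipelineConfig(n_cycles=200, min_freq=20, seed=1))
print(result.model.to_frame().round(4))
print(planted_recovery_report(cohort, result.model))
```

prints the fitted scoring model

```
                 coefficient      hr  hr_low  hr_high  p_value
term
LNC0000|LNC0001       1.1516  3.1632  2.2482   4.4505   0.0000
LNC0002|LNC0003       1.0338  2.8117  1.9056   4.1487   0.0000
LNC0004|LNC0005       0.6818  1.9774  1.4168   2.7597   0.0001
```

— exactly the three planted pairs (recovery 1.0, sign agreement 1.0);
the generator planted each at log-HR 1.0 and the coefficients estimate
that hazard ratio (`hr = exp(coefficient) ≈ e ≈ 2.7`). Evaluation on
the same run gives a 1-year AUC of 0.792, an optimal cutoff of 1.152
splitting 181 high- vs 219 low-risk patients, and a log-rank
p = 1.3e-31 between the groups. The planted downstream effects come
back with correct signs: NK cells r = +0.61 and regulatory T cells
r = +0.65, neutrophils r = −0.60 with the risk score, CTLA4 up /
CD274 down in the high-risk group, and only sunitinib among five drugs
shows a lower high-risk IC50 (p < 1e-4). The `examples/` scripts walk
through each capability and print these numbers.

There is also a thin CLI:

```bash
irlpair simulate --seed 1 --outdir cohort/
irlpair run-all --indir cohort/ --outdir results/ --seed 1
```

`run-all` writes every stage table plus `manifest.json` with the
counts surviving each filter.

## Reference tables

Two small published tables from the original TCGA-KIRC study ship with
the package (`irlpair.reference`): the 90-gene differential-expression
summary and the 27-pair multivariate Cox table. They pin down the
arithmetic conventions (logFC as the log2 ratio of linear-scale group
means; HR = exp(coefficient); the p < 0.05 rule giving the 16-pair
scoring model) and are verified by the test suite.

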