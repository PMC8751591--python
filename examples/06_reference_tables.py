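"""Consistency of the bundled TCGA-KIRC reference tables.

The original ccRCC study's differential-expression table (90 immune
lncRNAs) and multivariate Cox table (27 pairs) ship with the package.
Recomputing their internal arithmetic pins down the conventions this
package uses: logFC = log2 ratio of linear-scale group means,
HR = exp(coefficient), and the p < 0.05 retention rule giving the
16-pair scoring model.
"""

from irlpair.reference import de_table_consistency, pair_cox_consistency

de = de_table_consistency()
print(f"DE table rows                 : {len(de)}")
print(f"max |logFC - log2 mean ratio| : {de['log_fc_error'].max():.2e}")
print(f"down / up regulated           : {(de['log_fc'] < 0).sum()} / {(de['log_fc'] > 0).sum()}")

cox = pair_cox_consistency()
print(f"\npair Cox rows                 : {len(cox)}")
print(f"max |HR - exp(coef)|          : {cox['hr_error'].max():.2e}")
print(f"CI covers HR everywhere       : {cox['ci_covers_hr'].all()}")
print(f"pairs with p < 0.05           : {(cox['p_value'] < 0.05).sum()} of {len(cox)}")
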