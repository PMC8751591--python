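"""Published TCGA-KIRC reference tables bundled for consistency checks.

Two small tables from the original clear cell renal cell carcinoma study
that this pipeline re-implements are shipped with the package:

* the differential-expression summary of the 90 immune-related lncRNAs
  (linear-scale group means, log2 fold change, p, FDR), and
* the multivariate Cox table of the 27 candidate lncRNA pairs
  (coefficient, hazard ratio, 95% CI, p).

They are used to verify the pipeline's arithmetic conventions — that
logFC is the log2 ratio of linear-scale group means, that HR = exp(coef),
and that the p < 0.05 retention rule reproduces the published 16-pair
model — without needing the full TCGA cohort.
"""

from importlib import resources

import numpy as np
import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("irlpair.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_de_table() -> pd.DataFrame:
    """The 90-row differential-expression table (columns: lncRNA,
    normal_mean, tumor_mean, log_fc, p_value, fdr)."""
    return _load("kirc_de_irlncrna.tsv")


def load_reference_pair_cox_table() -> pd.DataFrame:
    """The 27-row multivariate Cox table over lncRNA pairs (columns:
    pair, coefficient, hr, hr_low, hr_high, p_value)."""
    return _load("kirc_pair_cox.tsv")


def de_table_consistency() -> pd.DataFrame:
    """Recompute log2(tumor_mean / normal_mean) for every reference row.

    Returns the table with columns ``log_fc_recomputed`` and
    ``log_fc_error`` added.
    """
    df = load_reference_de_table().copy()
    df["log_fc_recomputed"] = np.log2(df["tumor_mean"] / df["normal_mean"])
    df["log_fc_error"] = (df["log_fc_recomputed"] - df["log_fc"]).abs()
    return df


def pair_cox_consistency() -> pd.DataFrame:
    """Recompute exp(coefficient) for every reference pair row.

    Adds ``hr_recomputed``, ``hr_error`` and ``ci_covers_hr`` columns.
    """
    df = load_reference_pair_cox_table().copy()
    df["hr_recomputed"] = np.exp(df["coefficient"])
    df["hr_error"] = (df["hr_recomputed"] - df["hr"]).abs()
    df["ci_covers_hr"] = (df["hr"] >= df["hr_low"]) & (df["hr"] <= df["hr_high"])
    return df
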