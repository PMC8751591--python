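"""Immune-related lncRNA screening and differential expression.

Two filters, applied in order:

1. *Co-expression screen*: a lncRNA is immune-related if its Pearson
   correlation with at least one curated immune gene exceeds ``r_min``
   with two-sided p below ``p_max`` (t-test on n-2 df).
2. *Differential expression*: log2 fold change is the log2 ratio of the
   linear-scale tumor and normal group means; the p-value comes from a
   two-sided Wilcoxon rank-sum test between groups, adjusted by
   Benjamini-Hochberg. A gene is retained iff |logFC| > ``lfc_min`` and
   FDR < ``fdr_max`` (strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from irlpair.io_formats import ExpressionMatrix, NORMAL, TUMOR


@dataclass
class DEResult:
    gene_id: str
    normal_mean: float
    tumor_mean: float
    log_fc: float
    p_value: float
    fdr: float
    retained: bool


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (the FDR column)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_coexpression_screen(
    lnc_expr: ExpressionMatrix | pd.DataFrame,
    immune_expr: ExpressionMatrix | pd.DataFrame,
    r_min: float = 0.4,
    p_max: float = 0.001,
) -> pd.DataFrame:
    """Retain lncRNAs co-expressed with at least one immune gene.

    Both arguments are gene x sample matrices over the same samples.
    Returns one row per retained lncRNA with its best-correlated immune
    partner (largest r), that r, and the two-sided p-value of r.
    Zero-variance genes are skipped with a warning (r undefined).
    """
    L = lnc_expr.values if isinstance(lnc_expr, ExpressionMatrix) else lnc_expr
    M = immune_expr.values if isinstance(immune_expr, ExpressionMatrix) else immune_expr
    shared = L.columns.intersection(M.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for a correlation test")
    if M.shape[0] == 0:
        raise ValueError("immune gene set is empty")
    L = L[shared]
    M = M[shared]
    n = len(shared)

    l_arr = L.to_numpy(dtype=float)
    m_arr = M.to_numpy(dtype=float)
    l_sd = l_arr.std(axis=1)
    m_sd = m_arr.std(axis=1)
    for name in L.index[l_sd == 0]:
        warnings.warn(f"lncRNA {name!r} has zero variance; skipped", stacklevel=2)
    for name in M.index[m_sd == 0]:
        warnings.warn(f"immune gene {name!r} has zero variance; skipped", stacklevel=2)
    l_keep = l_sd > 0
    m_keep = m_sd > 0
    if not l_keep.any() or not m_keep.any():
        return pd.DataFrame(columns=["lncRNA", "partner", "r", "p_value"]).set_index("lncRNA")

    lz = (l_arr[l_keep] - l_arr[l_keep].mean(axis=1, keepdims=True)) / l_sd[l_keep, None]
    mz = (m_arr[m_keep] - m_arr[m_keep].mean(axis=1, keepdims=True)) / m_sd[m_keep, None]
    r = lz @ mz.T / n  # lnc x immune correlation matrix
    r = np.clip(r, -1.0, 1.0)
    # two-sided p from the t-distribution with n-2 df
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r * r, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)

    hit = (r > r_min) & (p < p_max)
    rows = []
    lnc_names = L.index[l_keep]
    immune_names = M.index[m_keep]
    for i, lnc in enumerate(lnc_names):
        if not hit[i].any():
            continue
        # best partner = largest r among the qualifying immune genes
        j = int(np.argmax(np.where(hit[i], r[i], -np.inf)))
        rows.append({"lncRNA": lnc, "partner": immune_names[j], "r": r[i, j], "p_value": p[i, j]})
    out = pd.DataFrame(rows, columns=["lncRNA", "partner", "r", "p_value"])
    return out.set_index("lncRNA")


def differential_expression(
    expr: ExpressionMatrix,
    lfc_min: float = 1.5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression on linear-scale values.

    Returns a table with one row per gene: normal_mean, tumor_mean,
    log_fc = log2(tumor_mean / normal_mean), Wilcoxon rank-sum p,
    BH-adjusted FDR and the retention flag
    ``|log_fc| > lfc_min and fdr < fdr_max``. Genes whose group mean is
    exactly zero get a +/-inf log_fc sentinel and are never retained.
    """
    tumor = expr.samples_in_group(TUMOR)
    normal = expr.samples_in_group(NORMAL)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("both groups need at least 2 samples")
    tv = expr.values[tumor].to_numpy(dtype=float)
    nv = expr.values[normal].to_numpy(dtype=float)
    tumor_mean = tv.mean(axis=1)
    normal_mean = nv.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_fc = np.log2(tumor_mean / normal_mean)
    zero_mean = (tumor_mean == 0) | (normal_mean == 0)
    if zero_mean.any():
        warnings.warn(
            f"{int(zero_mean.sum())} gene(s) with a zero group mean excluded from retention",
            stacklevel=2,
        )
        log_fc = np.where(zero_mean, np.where(tumor_mean >= normal_mean, np.inf, -np.inf), log_fc)

    p = np.empty(len(log_fc))
    for i in range(len(p)):
        if np.ptp(tv[i]) == 0 and np.ptp(nv[i]) == 0 and tv[i][0] == nv[i][0]:
            p[i] = 1.0
            continue
        p[i] = stats.mannwhitneyu(tv[i], nv[i], alternative="two-sided").pvalue
    fdr = bh_adjust(p)

    retained = (np.abs(log_fc) > lfc_min) & (fdr < fdr_max) & ~zero_mean & np.isfinite(log_fc)
    out = pd.DataFrame(
        {
            "normal_mean": normal_mean,
            "tumor_mean": tumor_mean,
            "log_fc": log_fc,
            "p_value": p,
            "fdr": fdr,
            "retained": retained,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    return out
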