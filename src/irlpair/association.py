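"""Downstream correlates of the risk model.

Clinical indicators use the chi-square test of independence on the
risk-group x level contingency table; score-vs-subgroup contrasts use
the Wilcoxon rank-sum test (Kruskal-Wallis above two levels); immune
infiltration scores use the Pearson correlation with the risk score;
checkpoint-gene expression and drug IC50 values use two-group Wilcoxon
tests between the high- and low-risk groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from irlpair.io_formats import ExpressionMatrix
from irlpair.screen import bh_adjust

#: Immune checkpoint genes tested between risk groups by default.
CHECKPOINT_GENES = ("CD274", "CTLA4", "HAVCR2", "LAG3", "LGALS9", "PDCD1", "PDCD1LG2", "TIGIT")

#: Alternate symbols for the same checkpoint genes.
GENE_ALIASES = {"GAL9": "LGALS9", "LGALS9": "GAL9", "TIM-3": "HAVCR2", "HAVCR2": "TIM-3", "PD-L1": "CD274", "PD-1": "PDCD1", "PD-L2": "PDCD1LG2"}


@dataclass
class AssociationRecord:
    variable: str
    method: str  # chi-square | wilcoxon | kruskal | pearson
    statistic: float
    p_value: float
    estimate: float  # r, median difference, or 0 for chi-square
    note: str = ""


def clinical_association(groups: pd.Series, covariate: pd.Series) -> AssociationRecord:
    """Chi-square test of independence between risk group and a
    categorical clinical covariate (no continuity correction)."""
    shared = groups.index.intersection(covariate.index)
    table = pd.crosstab(groups.loc[shared], covariate.loc[shared].astype(str))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 covariate levels with nonzero counts")
    chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    note = ""
    if (expected < 1).mean() > 0.2:
        note = "more than 20% of expected counts below 1; chi-square approximation unreliable"
        warnings.warn(note, stacklevel=2)
    return AssociationRecord(
        variable=str(covariate.name or "covariate"),
        method="chi-square",
        statistic=float(chi2),
        p_value=float(p),
        estimate=0.0,
        note=note,
    )


def _wilcoxon_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact when both groups are small (<= 10)
    and tie-free, normal approximation otherwise."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def score_subgroup_test(scores: pd.Series, labels: pd.Series) -> AssociationRecord:
    """Compare risk scores across subgroup labels: Wilcoxon rank-sum for
    two levels, Kruskal-Wallis for more."""
    shared = scores.index.intersection(labels.index)
    s = scores.loc[shared].astype(float)
    lab = labels.loc[shared].astype(str)
    levels = sorted(lab.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 subgroup levels")
    samples = [s[lab == lv].to_numpy() for lv in levels]
    if len(levels) == 2:
        stat, p = _wilcoxon_two_sided(samples[0], samples[1])
        est = float(np.median(samples[1]) - np.median(samples[0]))
        method = "wilcoxon"
    else:
        res = stats.kruskal(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
        est = 0.0
        method = "kruskal"
    return AssociationRecord(
        variable=str(labels.name or "subgroup"),
        method=method,
        statistic=stat,
        p_value=p,
        estimate=est,
    )


def infiltration_correlation(
    scores: pd.Series,
    infiltration: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each infiltration column with the risk
    score. Returns every testable column with r, p, a BH-adjusted column
    and the retained flag (unadjusted p < ``p_max``, as screened)."""
    shared = scores.index.intersection(infiltration.index)
    rows = []
    for col in infiltration.columns:
        v = infiltration.loc[shared, col].astype(float)
        ok = v.notna()
        if ok.sum() < 3:
            warnings.warn(f"infiltration column {col!r} has <3 paired observations; skipped", stacklevel=2)
            continue
        x = scores.loc[shared][ok].to_numpy(dtype=float)
        y = v[ok].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            warnings.warn(f"infiltration column {col!r} has zero variance; skipped", stacklevel=2)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"variable": col, "r": float(r), "p_value": float(p), "n": int(ok.sum())})
    out = pd.DataFrame(rows, columns=["variable", "r", "p_value", "n"]).set_index("variable")
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out["retained"] = out["p_value"] < p_max
    else:
        out["fdr"] = []
        out["retained"] = []
    return out


def _resolve_genes(gene_ids, wanted) -> tuple[dict, list]:
    """Map wanted symbols to matrix rows, honouring known aliases."""
    present = {}
    missing = []
    index = set(gene_ids)
    for g in wanted:
        if g in index:
            present[g] = g
        elif GENE_ALIASES.get(g) in index:
            present[g] = GENE_ALIASES[g]
        else:
            missing.append(g)
    return present, missing


def checkpoint_expression_test(
    expr: ExpressionMatrix,
    groups: pd.Series,
    genes=CHECKPOINT_GENES,
) -> tuple[list[AssociationRecord], list[str]]:
    """Per-gene Wilcoxon test of expression between high/low risk groups.

    Returns (records, missing genes). The estimate is the high-minus-low
    median difference; its sign is the direction of the shift.
    """
    present, missing = _resolve_genes(expr.gene_ids, genes)
    shared = groups.index.intersection(expr.values.columns)
    g = groups.loc[shared]
    records = []
    for symbol, row_id in present.items():
        v = expr.values.loc[row_id, shared].astype(float)
        hi = v[g == "high"].to_numpy()
        lo = v[g == "low"].to_numpy()
        if len(hi) == 0 or len(lo) == 0:
            raise ValueError("both risk groups must be non-empty")
        stat, p = _wilcoxon_two_sided(hi, lo)
        records.append(
            AssociationRecord(
                variable=symbol,
                method="wilcoxon",
                statistic=stat,
                p_value=p,
                estimate=float(np.median(hi) - np.median(lo)),
            )
        )
    return records, missing


def drug_sensitivity_test(ic50: pd.DataFrame, groups: pd.Series) -> list[AssociationRecord]:
    """Per-drug Wilcoxon test of IC50 between high/low risk groups.

    A lower high-risk median IC50 (negative estimate) means the
    high-risk group is more sensitive to the drug. Drugs with no data
    are skipped; a drug with fewer than 2 observations in a group is an
    error, as the test is meaningless there.
    """
    shared = groups.index.intersection(ic50.index)
    g = groups.loc[shared]
    records = []
    for drug in ic50.columns:
        v = ic50.loc[shared, drug].astype(float)
        ok = v.notna()
        if ok.sum() == 0:
            warnings.warn(f"drug {drug!r} has no IC50 values; skipped", stacklevel=2)
            continue
        hi = v[ok & (g == "high")].to_numpy()
        lo = v[ok & (g == "low")].to_numpy()
        if len(hi) < 2 or len(lo) < 2:
            raise ValueError(f"drug {drug!r}: need >= 2 samples per risk group")
        stat, p = _wilcoxon_two_sided(hi, lo)
        records.append(
            AssociationRecord(
                variable=drug,
                method="wilcoxon",
                statistic=stat,
                p_value=p,
                estimate=float(np.median(hi) - np.median(lo)),
                note="higher sensitivity in high-risk group" if np.median(hi) < np.median(lo) else "",
            )
        )
    return records


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"variable": r.variable, "method": r.method, "statistic": r.statistic,
             "p_value": r.p_value, "estimate": r.estimate, "note": r.note}
            for r in records
        ],
        columns=["variable", "method", "statistic", "p_value", "estimate", "note"],
    ).set_index("variable")
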