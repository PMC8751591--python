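"""Time-dependent ROC, optimal cutoff, and risk-group survival analysis.

The ROC at a horizon t uses the cumulative-case / dynamic-control
definition: cases are patients with an observed event by t, controls are
patients still at risk beyond t. Censoring before t is handled by
inverse-probability-of-censoring weights from the Kaplan-Meier estimate
of the censoring distribution, so on uncensored data the curve reduces
to the empirical ROC and the trapezoidal AUC equals the Mann-Whitney
statistic of scores (cases vs controls).

The optimal cutoff maximises sensitivity + specificity (the Youden
criterion) by exhaustive scan over the observed score values; ties are
broken toward the smaller cutoff, which flags more patients high-risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from irlpair.io_formats import SurvivalTable

YEAR_DAYS = 365
DEFAULT_HORIZONS = (365, 1095, 1825)  # 1, 3, 5 years


@dataclass
class TimeDependentROC:
    horizon: float
    thresholds: np.ndarray  # ascending, with -inf/+inf endpoints
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    horizon: float


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    return kmf


def td_roc(scores: pd.Series, survival: SurvivalTable, horizon_days: float) -> TimeDependentROC:
    """Time-dependent ROC of ``scores`` for event-by-horizon status."""
    shared = [p for p in survival.patient_ids if p in scores.index]
    x = scores.loc[shared].to_numpy(dtype=float)
    t = survival.data.loc[shared, "time"].to_numpy(dtype=float)
    e = survival.data.loc[shared, "event"].to_numpy(dtype=int)

    case = (t <= horizon_days) & (e == 1)
    control = t > horizon_days
    if case.sum() == 0:
        raise ValueError(f"no events before horizon {horizon_days}; ROC undefined")
    if control.sum() == 0:
        raise ValueError(f"no subjects at risk beyond horizon {horizon_days}; ROC undefined")

    G = _censoring_survival(t, e)
    g_case = G.predict(np.nextafter(t[case], -np.inf)).to_numpy(dtype=float)
    g_case = np.maximum(g_case, np.min(g_case[g_case > 0], initial=1.0) if (g_case > 0).any() else 1.0)
    w_case = 1.0 / g_case
    w_case /= w_case.sum()

    thresholds = np.concatenate([[-np.inf], np.unique(x), [np.inf]])
    xc, xn = x[case], x[control]
    # P(score > c | case), weighted; P(score <= c | control)
    sens = np.array([(w_case * (xc > c)).sum() for c in thresholds])
    spec = np.array([(xn <= c).mean() for c in thresholds])
    # traverse thresholds downward: fpr and sensitivity both rise
    # monotonically, tracing the ROC from (0, 0) to (1, 1)
    fpr = 1 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return TimeDependentROC(
        horizon=float(horizon_days),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_cases=int(case.sum()),
        n_controls=int(control.sum()),
    )


def optimal_cutoff(roc: TimeDependentROC) -> CutoffResult:
    """Youden-style cutoff: maximise sensitivity + specificity by
    exhaustive scan; ties go to the smaller cutoff."""
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    youden = roc.sensitivity[finite] + roc.specificity[finite]
    if len(thr) == 0:
        raise ValueError("ROC has no finite thresholds")
    if np.allclose(youden, youden[0]):
        warnings.warn("flat ROC: sensitivity + specificity constant; returning first threshold", stacklevel=2)
        best = 0
    else:
        best = int(np.argmax(youden))  # argmax takes the first (smallest cutoff) on ties
    return CutoffResult(
        cutoff=float(thr[best]),
        sensitivity=float(roc.sensitivity[finite][best]),
        specificity=float(roc.specificity[finite][best]),
        horizon=roc.horizon,
    )


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """High/low risk groups: score > cutoff is high risk."""
    return pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index, name="risk_group")


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a (time, survival) step table."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), event_observed=np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() == 0 or eb.sum() == 0:
        warnings.warn("a group has zero events; log-rank test is weakly informative", stacklevel=2)
    res = _ll_logrank(np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float), ea, eb)
    return float(res.test_statistic), float(res.p_value)


_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5}


def encode_covariate(values: pd.Series) -> pd.Series:
    """Ordinal-encode a clinical covariate for Cox regression.

    Numeric strings parse as numbers; stage-like roman numerals map
    I..V -> 1..5; labels with a trailing integer (G2, T3, N0, M1,
    "stage ii") use that integer; female/male -> 0/1; "unknown" becomes
    NaN (such patients are excluded from Cox fits only); anything else
    falls back to alphabetical category codes.
    """
    s = values.astype(str).str.strip()
    out = pd.to_numeric(s, errors="coerce")
    todo = out.isna()
    for idx in s.index[todo]:
        raw = s.loc[idx]
        low = raw.lower()
        if low in ("unknown", "nan", "na", ""):
            continue
        token = low.split()[-1] if " " in low else low
        if token in _ROMAN:
            out.loc[idx] = _ROMAN[token]
        elif token in ("female", "f"):
            out.loc[idx] = 0
        elif token in ("male", "m"):
            out.loc[idx] = 1
        else:
            digits = "".join(ch for ch in token if ch.isdigit())
            if digits:
                out.loc[idx] = int(digits)
    still = out.isna() & ~s.str.lower().isin(["unknown", "nan", "na", ""])
    if still.any():
        cats = sorted(s[still].unique())
        for idx in s.index[still]:
            out.loc[idx] = cats.index(s.loc[idx])
    return out.astype(float)


def independent_predictor_analysis(
    scores: pd.Series,
    survival: SurvivalTable,
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate and multivariate Cox over clinical covariates + score.

    Returns (univariate table, multivariate table), each with columns
    coefficient, hr, hr_low, hr_high, p_value indexed by term. Patients
    with an unknown value are excluded per-fit; aliased covariates are
    dropped from the joint fit deterministically.
    """
    from irlpair.survival_model import _drop_aliased, _fit_single_cox

    if covariates is None:
        covariates = survival.covariate_names
    shared = [p for p in survival.patient_ids if p in scores.index]
    y = survival.data.loc[shared, ["time", "event"]]
    design = pd.DataFrame(index=y.index)
    for cov in covariates:
        design[cov] = encode_covariate(survival.data.loc[shared, cov])
    design["risk_score"] = scores.loc[shared].astype(float)

    uni_rows = []
    for term in design.columns:
        x = design[term].dropna()
        row = _fit_single_cox(x, y.loc[x.index])
        if row is not None:
            uni_rows.append(
                {"term": row.term, "coefficient": row.coefficient, "hr": row.hr,
                 "hr_low": row.hr_low, "hr_high": row.hr_high, "p_value": row.p_value}
            )
    uni = pd.DataFrame(uni_rows, columns=["term", "coefficient", "hr", "hr_low", "hr_high", "p_value"]).set_index("term")

    complete = design.dropna()
    keepable = complete.loc[:, complete.nunique() > 1]
    X = _drop_aliased(keepable)
    df = pd.concat([y.loc[complete.index], X], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    multi = pd.DataFrame(
        {
            "coefficient": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "hr_low": np.exp(summ["coef lower 95%"]),
            "hr_high": np.exp(summ["coef upper 95%"]),
            "p_value": summ["p"],
        }
    )
    multi.index.name = "term"
    return uni, multi
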