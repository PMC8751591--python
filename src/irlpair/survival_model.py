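"""Prognostic pair selection and the linear risk score.

The selection cascade:

1. *Univariate Cox screen* — one single-covariate proportional-hazards
   fit per pair indicator (Efron tie handling, Wald p); keep p < 0.01.
2. *Resampled LASSO-Cox frequency selection* — for each of ``n_cycles``
   random cycles, draw a bootstrap resample of patients, fit an
   L1-penalised Cox path, choose the penalty by K-fold cross-validated
   partial likelihood within the cycle, and record which pairs have
   nonzero coefficients; keep pairs selected in more than ``min_freq``
   cycles.
3. *Multivariate Cox* — one joint fit over the selected pairs; the
   scoring model keeps the pairs with multivariate p < 0.05 (the full
   fitted table is also reported).

The per-patient risk score is the exact linear form
``sum_i coefficient_i * alpha_i`` over the retained pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from irlpair.io_formats import SurvivalTable
from irlpair.pairing import PairIndicatorMatrix

logger = logging.getLogger(__name__)


@dataclass
class CoxRow:
    term: str
    coefficient: float
    hr: float
    hr_low: float
    hr_high: float
    p_value: float


@dataclass
class RiskModel:
    """Retained lncRNA pairs with their multivariate Cox coefficients.

    ``rows`` are the scoring pairs (multivariate p below the retention
    threshold); ``full_table`` holds every fitted pair for reporting.
    """

    rows: list[CoxRow]
    retention_rule: str
    training_samples: list[str]
    full_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def pair_ids(self) -> list[str]:
        return [r.term for r in self.rows]

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series({r.term: r.coefficient for r in self.rows}, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "coefficient": r.coefficient,
                    "hr": r.hr,
                    "hr_low": r.hr_low,
                    "hr_high": r.hr_high,
                    "p_value": r.p_value,
                }
                for r in self.rows
            ]
        ).set_index("term")


def _cox_design(pairs: PairIndicatorMatrix, survival: SurvivalTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patients x pairs design and the aligned (time, event) frame."""
    shared = [p for p in survival.patient_ids if p in pairs.indicators.columns]
    if not shared:
        raise ValueError("pairs and survival share no patients")
    X = pairs.indicators[shared].T.astype(float)
    y = survival.data.loc[shared, ["time", "event"]]
    return X, y


def _fit_single_cox(x: pd.Series, y: pd.DataFrame) -> CoxRow | None:
    df = y.copy()
    df["x"] = x
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            return None
    s = cph.summary.loc["x"]
    if not np.isfinite(s["coef"]) or not np.isfinite(s["p"]):
        return None
    return CoxRow(
        term=str(x.name),
        coefficient=float(s["coef"]),
        hr=float(np.exp(s["coef"])),
        hr_low=float(np.exp(s["coef lower 95%"])),
        hr_high=float(np.exp(s["coef upper 95%"])),
        p_value=float(s["p"]),
    )


def univariate_cox_screen(
    pairs: PairIndicatorMatrix,
    survival: SurvivalTable,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Single-covariate Cox fit per pair; returns the full table with a
    ``retained`` flag for p < ``p_max``.

    Constant pairs and non-convergent fits (e.g. monotone likelihood
    under perfect separation) are dropped with a warning.
    """
    X, y = _cox_design(pairs, survival)
    if int(y["event"].sum()) < 10:
        warnings.warn("fewer than 10 events; univariate screen is unreliable", stacklevel=2)
    rows = []
    for pid in X.columns:
        x = X[pid]
        if x.nunique() < 2:
            warnings.warn(f"pair {pid!r} is constant over patients; dropped", stacklevel=2)
            continue
        row = _fit_single_cox(x, y)
        if row is None:
            warnings.warn(f"univariate Cox did not converge for pair {pid!r}; dropped", stacklevel=2)
            continue
        rows.append(row)
    out = pd.DataFrame(
        [
            {
                "term": r.term,
                "coefficient": r.coefficient,
                "hr": r.hr,
                "hr_low": r.hr_low,
                "hr_high": r.hr_high,
                "p_value": r.p_value,
            }
            for r in rows
        ],
        columns=["term", "coefficient", "hr", "hr_low", "hr_high", "p_value"],
    ).set_index("term")
    out["retained"] = out["p_value"] < p_max
    logger.info("univariate screen: %d/%d pairs retained at p<%g", int(out["retained"].sum()), len(X.columns), p_max)
    return out


def _breslow_loglik(time, event, eta) -> float:
    """Breslow partial log-likelihood of linear predictors ``eta``."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    t, d, e = time[order], event[order], eta[order]
    log_cumsum = np.logaddexp.accumulate(e)
    # risk set of subject i = all with t_j >= t_i; with decreasing sort and
    # ties grouped, take the last index sharing the same time
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        denom = log_cumsum[j]
        for k in range(i, j + 1):
            if d[k]:
                ll += e[k] - denom
        i = j + 1
    return ll


def lasso_frequency_selection(
    candidates: pd.DataFrame,
    survival: SurvivalTable,
    n_cycles: int = 1000,
    min_freq: int = 100,
    cv_folds: int = 10,
    seed: int | None = None,
    n_alphas: int = 20,
) -> pd.DataFrame:
    """Bootstrap-resampled cross-validated LASSO-Cox selection frequency.

    ``candidates`` is a patients x pairs 0/1 design (e.g. the univariate
    survivors). Each cycle resamples patients with replacement, fits an
    L1-penalised Cox path, picks the penalty maximising ``cv_folds``-fold
    cross-validated Breslow partial likelihood within the resample, and
    records the nonzero support. Returns a frequency table with a
    ``selected`` flag for frequency > ``min_freq``. Deterministic for a
    fixed seed.
    """
    if candidates.shape[1] < 2:
        raise ValueError("need at least 2 candidate pairs for LASSO selection")
    shared = [p for p in survival.patient_ids if p in candidates.index]
    if len(shared) < 20:
        raise ValueError("need at least 20 patients for resampled selection")
    X = candidates.loc[shared].to_numpy(dtype=float)
    yt = survival.data.loc[shared, "time"].to_numpy(dtype=float)
    ye = survival.data.loc[shared, "event"].to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    counts = np.zeros(candidates.shape[1], dtype=int)
    n = len(shared)

    for _ in range(n_cycles):
        idx = rng.integers(0, n, size=n)
        Xb, tb, eb = X[idx], yt[idx], ye[idx]
        if eb.sum() < 2:
            continue
        keep = Xb.std(axis=0) > 0
        if keep.sum() < 2:
            continue
        Xk = Xb[:, keep]
        yb = Surv.from_arrays(event=eb, time=tb)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01)
                path.fit(Xk, yb)
        except (ValueError, ArithmeticError):
            continue
        alphas = path.alphas_
        # K-fold CV of the held-out Breslow partial likelihood
        fold = rng.permutation(n) % cv_folds
        cv_ll = np.zeros(len(alphas))
        valid = np.ones(len(alphas), dtype=bool)
        for f in range(cv_folds):
            tr, te = fold != f, fold == f
            if eb[te].sum() == 0 or eb[tr].sum() < 2:
                continue
            ktr = Xk[tr].std(axis=0) > 0
            if ktr.sum() == 0:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
                    m.fit(Xk[tr][:, ktr], Surv.from_arrays(event=eb[tr], time=tb[tr]))
            except (ValueError, ArithmeticError):
                continue
            coefs = np.zeros((Xk.shape[1], len(alphas)))
            fitted_alphas = list(m.alphas_)
            cmat = m.coef_  # features x fitted alphas
            for ai, a in enumerate(alphas):
                if a in fitted_alphas:
                    coefs[np.nonzero(ktr)[0], ai] = cmat[:, fitted_alphas.index(a)]
                else:
                    valid[ai] = False
            eta = Xk[te] @ coefs
            for ai in range(len(alphas)):
                if valid[ai]:
                    cv_ll[ai] += _breslow_loglik(tb[te], eb[te], eta[:, ai])
        if not valid.any():
            continue
        best = int(np.argmax(np.where(valid, cv_ll, -np.inf)))
        support = np.abs(path.coef_[:, best]) > 0
        counts[np.nonzero(keep)[0][support]] += 1

    out = pd.DataFrame(
        {"frequency": counts},
        index=pd.Index(candidates.columns, name="term"),
    )
    out["selected"] = out["frequency"] > min_freq
    if not out["selected"].any():
        logger.warning("LASSO frequency selection retained no pairs at freq>%d", min_freq)
    return out


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop linearly dependent columns, keeping the lexicographically
    earliest representatives; warns about what was dropped."""
    cols = sorted(X.columns)
    kept: list[str] = []
    basis = np.empty((X.shape[0], 0))
    for c in cols:
        v = X[c].to_numpy(dtype=float)[:, None]
        trial = np.hstack([basis, v])
        if np.linalg.matrix_rank(trial) > basis.shape[1]:
            basis = trial
            kept.append(c)
        else:
            warnings.warn(f"covariate {c!r} is aliased with earlier covariates; dropped", stacklevel=3)
    return X[[c for c in X.columns if c in kept]]


def multivariate_cox(
    selected: PairIndicatorMatrix | pd.DataFrame,
    survival: SurvivalTable,
    retain_p: float = 0.05,
) -> RiskModel:
    """Joint Cox fit over the selected pairs; the scoring model keeps
    pairs with multivariate p < ``retain_p``.

    ``selected`` is either a PairIndicatorMatrix restricted to the
    selected pairs or a patients x pairs design frame. Aliased (linearly
    dependent) covariates are dropped deterministically before fitting.
    """
    if isinstance(selected, PairIndicatorMatrix):
        X, y = _cox_design(selected, survival)
    else:
        shared = [p for p in survival.patient_ids if p in selected.index]
        X = selected.loc[shared].astype(float)
        y = survival.data.loc[shared, ["time", "event"]]
    if X.shape[1] == 0:
        raise ValueError("no pairs supplied to the multivariate fit")
    n_events = int(y["event"].sum())
    if n_events < X.shape[1]:
        warnings.warn(
            f"only {n_events} events for {X.shape[1]} covariates; estimates may be unstable",
            stacklevel=2,
        )
    X = _drop_aliased(X)
    df = pd.concat([y, X], axis=1)
    cph = CoxPHFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            # fall back to a whisper of ridge for ill-conditioned designs
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    full = pd.DataFrame(
        {
            "coefficient": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "hr_low": np.exp(summ["coef lower 95%"]),
            "hr_high": np.exp(summ["coef upper 95%"]),
            "p_value": summ["p"],
        }
    )
    full.index.name = "term"
    rows = [
        CoxRow(term=t, coefficient=float(r["coefficient"]), hr=float(r["hr"]),
               hr_low=float(r["hr_low"]), hr_high=float(r["hr_high"]), p_value=float(r["p_value"]))
        for t, r in full.iterrows()
        if r["p_value"] < retain_p
    ]
    logger.info("multivariate Cox: %d/%d pairs retained at p<%g", len(rows), len(full), retain_p)
    return RiskModel(
        rows=rows,
        retention_rule=f"multivariate p < {retain_p}",
        training_samples=list(y.index),
        full_table=full,
    )


def risk_score(model: RiskModel, pairs: PairIndicatorMatrix) -> pd.Series:
    """Per-sample risk score: sum of coefficient_i * indicator_i over the
    model's retained pairs. Exact linear arithmetic."""
    missing = [p for p in model.pair_ids if p not in pairs.indicators.index]
    if missing:
        raise ValueError(f"pairs missing from indicator matrix: {missing}")
    if not model.rows:
        return pd.Series(0.0, index=pairs.indicators.columns, name="risk_score")
    coef = model.coefficients
    sub = pairs.indicators.loc[coef.index].astype(float)
    scores = sub.mul(coef, axis=0).sum(axis=0)
    scores.name = "risk_score"
    return scores
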