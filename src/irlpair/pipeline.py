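"""End-to-end orchestration of the pair-signature pipeline.

Stages: immune co-expression screen -> differential expression ->
pair encoding with the effective-match filter -> univariate Cox screen
-> resampled LASSO-Cox frequency selection -> multivariate Cox ->
risk scores -> time-dependent ROC / cutoff / Kaplan-Meier -> clinical,
infiltration, checkpoint and drug associations.

The run manifest records the seed, every threshold, and the counts
surviving each filter, so a run is auditable stage by stage. A single
global seed is expanded into per-stage substreams; only the LASSO
resampling consumes randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from irlpair import association as assoc
from irlpair import evaluation as ev
from irlpair.datagen import SyntheticCohort
from irlpair.io_formats import (
    ExpressionMatrix,
    GeneAnnotation,
    SurvivalTable,
    TUMOR,
    write_score_table,
)
from irlpair.pairing import PairIndicatorMatrix, build_effective_pairs
from irlpair.screen import differential_expression, pearson_coexpression_screen
from irlpair.survival_model import (
    RiskModel,
    lasso_frequency_selection,
    multivariate_cox,
    risk_score,
    univariate_cox_screen,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with published defaults."""

    r_min: float = 0.4            # co-expression screen: Pearson r
    coexpr_p_max: float = 0.001   # co-expression screen: p
    lfc_min: float = 1.5          # DE filter: |log2 fold change|
    fdr_max: float = 0.05         # DE filter: BH FDR
    pair_low: float = 0.2         # effective-match one-fraction bounds
    pair_high: float = 0.8
    univariate_p_max: float = 0.01
    n_cycles: int = 1000          # LASSO resampling cycles
    min_freq: int = 100           # selection-frequency threshold
    cv_folds: int = 10
    retain_p: float = 0.05        # multivariate retention rule
    horizons: tuple = (365, 1095, 1825)
    cutoff_horizon: int = 365     # horizon used for the optimal cutoff
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "horizons" in raw:
            raw["horizons"] = tuple(raw["horizons"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    immune_lnc: pd.DataFrame | None = None
    de_table: pd.DataFrame | None = None
    pairs: PairIndicatorMatrix | None = None
    univariate: pd.DataFrame | None = None
    lasso_freq: pd.DataFrame | None = None
    model: RiskModel | None = None
    scores: pd.Series | None = None
    rocs: dict = field(default_factory=dict)
    cutoff: ev.CutoffResult | None = None
    groups: pd.Series | None = None
    logrank: tuple | None = None
    clinical_cox: tuple | None = None  # (univariate, multivariate) tables
    clinical_assoc: pd.DataFrame | None = None
    subgroup_tests: pd.DataFrame | None = None
    infiltration_corr: pd.DataFrame | None = None
    checkpoint_tests: pd.DataFrame | None = None
    checkpoint_missing: list = field(default_factory=list)
    drug_tests: pd.DataFrame | None = None
    stopped_at: str | None = None
    message: str = ""
    manifest: dict = field(default_factory=dict)

    @property
    def completed(self) -> bool:
        return self.stopped_at is None


def _stop(result: PipelineResult, stage: str, message: str) -> PipelineResult:
    result.stopped_at = stage
    result.message = message
    result.manifest["stopped_at"] = stage
    result.manifest["message"] = message
    logger.warning("pipeline stopped at %s: %s", stage, message)
    return result


def run_full_pipeline(
    expression: ExpressionMatrix,
    annotation: GeneAnnotation,
    immune_genes: set,
    survival: SurvivalTable,
    config: PipelineConfig | None = None,
    infiltration: pd.DataFrame | None = None,
    ic50: pd.DataFrame | None = None,
    outdir=None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write all stage
    outputs and a machine-readable manifest under ``outdir``."""
    cfg = config or PipelineConfig()
    result = PipelineResult(config=cfg)
    counts: dict = {}
    manifest = result.manifest
    manifest["seed"] = cfg.seed
    manifest["config"] = dataclasses.asdict(cfg)
    manifest["counts"] = counts

    # --- split biotypes --------------------------------------------------
    lnc_genes = [g for g in expression.gene_ids if annotation.biotype(g) == "lncRNA"]
    name_to_id = {}
    for gid, row in annotation.table.iterrows():
        name_to_id.setdefault(row["gene_name"], gid)
    immune_ids = [
        g
        for g in expression.gene_ids
        if annotation.biotype(g) == "protein_coding" and (g in immune_genes or annotation.table.at[g, "gene_name"] in immune_genes)
    ]
    counts["lncRNA_genes"] = len(lnc_genes)
    counts["immune_mrna_genes"] = len(immune_ids)
    if not lnc_genes:
        return _finalize(_stop(result, "screen", "no lncRNA genes in the expression matrix"), outdir)
    if not immune_ids:
        return _finalize(_stop(result, "screen", "no immune mRNA genes in the expression matrix"), outdir)

    # --- immune co-expression screen ------------------------------------
    lnc_expr = expression.subset_genes(lnc_genes)
    immune_expr = expression.subset_genes(immune_ids)
    result.immune_lnc = pearson_coexpression_screen(
        lnc_expr, immune_expr, r_min=cfg.r_min, p_max=cfg.coexpr_p_max
    )
    counts["immune_related_lncRNA"] = len(result.immune_lnc)
    if len(result.immune_lnc) == 0:
        return _finalize(_stop(result, "screen", "no immune-related lncRNAs at the co-expression thresholds"), outdir)

    # --- differential expression ----------------------------------------
    ir_expr = expression.subset_genes(result.immune_lnc.index)
    result.de_table = differential_expression(ir_expr, lfc_min=cfg.lfc_min, fdr_max=cfg.fdr_max)
    de_genes = list(result.de_table.index[result.de_table["retained"]])
    counts["de_immune_lncRNA"] = len(de_genes)
    if len(de_genes) < 2:
        return _finalize(_stop(result, "pairing", f"only {len(de_genes)} DE immune lncRNA(s); need >= 2 to form pairs"), outdir)

    # --- pair encoding ----------------------------------------------------
    result.pairs = build_effective_pairs(
        expression.subset_genes(de_genes), low=cfg.pair_low, high=cfg.pair_high
    )
    counts["candidate_pairs"] = result.pairs.n_candidates
    counts["effective_pairs"] = len(result.pairs.pair_ids)
    if len(result.pairs.pair_ids) == 0:
        return _finalize(_stop(result, "pairing", "no effective pairs after the one-fraction filter"), outdir)

    # --- univariate Cox screen -------------------------------------------
    result.univariate = univariate_cox_screen(result.pairs, survival, p_max=cfg.univariate_p_max)
    candidates = list(result.univariate.index[result.univariate["retained"]])
    counts["univariate_survivors"] = len(candidates)
    if len(candidates) == 0:
        return _finalize(_stop(result, "fit", "no pairs survive the univariate Cox screen"), outdir)

    # --- LASSO frequency selection ---------------------------------------
    X = result.pairs.indicators.loc[candidates].T.astype(float)
    X = X.loc[[p for p in survival.patient_ids if p in X.index]]
    lasso_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31))
    if len(candidates) >= 2:
        result.lasso_freq = lasso_frequency_selection(
            X, survival, n_cycles=cfg.n_cycles, min_freq=cfg.min_freq,
            cv_folds=cfg.cv_folds, seed=lasso_seed,
        )
        selected = list(result.lasso_freq.index[result.lasso_freq["selected"]])
        if not selected:
            logger.warning("empty LASSO selection; falling back to univariate survivors")
            selected = candidates
    else:
        # a single candidate cannot enter a LASSO path; pass it through
        result.lasso_freq = pd.DataFrame({"frequency": [cfg.n_cycles], "selected": [True]},
                                         index=pd.Index(candidates, name="term"))
        selected = candidates
    counts["lasso_selected"] = len(selected)

    # --- multivariate Cox and risk scores --------------------------------
    result.model = multivariate_cox(X[selected], survival, retain_p=cfg.retain_p)
    counts["model_pairs"] = len(result.model.rows)
    if not result.model.rows:
        return _finalize(_stop(result, "fit", "no pairs reach multivariate significance; no scoring model"), outdir)
    result.scores = risk_score(result.model, result.pairs).loc[
        [p for p in survival.patient_ids if p in result.pairs.indicators.columns]
    ]

    # --- evaluation -------------------------------------------------------
    for h in cfg.horizons:
        try:
            result.rocs[h] = ev.td_roc(result.scores, survival, h)
        except ValueError as exc:
            logger.warning("ROC at %s days unavailable: %s", h, exc)
    if cfg.cutoff_horizon not in result.rocs:
        return _finalize(_stop(result, "evaluate", f"ROC at the cutoff horizon ({cfg.cutoff_horizon} d) unavailable"), outdir)
    result.cutoff = ev.optimal_cutoff(result.rocs[cfg.cutoff_horizon])
    result.groups = ev.assign_risk_groups(result.scores, result.cutoff.cutoff)
    counts["high_risk"] = int((result.groups == "high").sum())
    counts["low_risk"] = int((result.groups == "low").sum())

    surv = survival.data
    hi = surv.loc[result.groups.index[result.groups == "high"]]
    lo = surv.loc[result.groups.index[result.groups == "low"]]
    if len(hi) and len(lo):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result.logrank = ev.logrank_test(hi["time"], hi["event"], lo["time"], lo["event"])
    result.clinical_cox = ev.independent_predictor_analysis(result.scores, survival)

    # --- associations -----------------------------------------------------
    recs, sub_recs = [], []
    for cov in survival.covariate_names:
        try:
            recs.append(assoc.clinical_association(result.groups, surv[cov]))
        except ValueError as exc:
            logger.warning("clinical association for %s skipped: %s", cov, exc)
        try:
            sub_recs.append(assoc.score_subgroup_test(result.scores, surv[cov]))
        except ValueError as exc:
            logger.warning("subgroup test for %s skipped: %s", cov, exc)
    result.clinical_assoc = assoc.records_to_frame(recs)
    result.subgroup_tests = assoc.records_to_frame(sub_recs)
    if infiltration is not None:
        result.infiltration_corr = assoc.infiltration_correlation(result.scores, infiltration)
    cp_records, cp_missing = assoc.checkpoint_expression_test(expression, result.groups)
    result.checkpoint_tests = assoc.records_to_frame(cp_records)
    result.checkpoint_missing = cp_missing
    if ic50 is not None:
        result.drug_tests = assoc.records_to_frame(assoc.drug_sensitivity_test(ic50, result.groups))

    return _finalize(result, outdir)


def run_on_cohort(cohort: SyntheticCohort, config: PipelineConfig | None = None, outdir=None) -> PipelineResult:
    """Convenience wrapper: run the full pipeline on a synthetic cohort."""
    return run_full_pipeline(
        cohort.expression,
        cohort.annotation,
        cohort.immune_genes,
        cohort.survival,
        config=config,
        infiltration=cohort.infiltration,
        ic50=cohort.ic50,
        outdir=outdir,
    )


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def _finalize(result: PipelineResult, outdir) -> PipelineResult:
    m = result.manifest
    if result.scores is not None:
        m["score_hash"] = hashlib.sha256(
            np.round(result.scores.to_numpy(), 10).tobytes()
        ).hexdigest()[:16]
    if result.model is not None:
        m["model_hash"] = _hash_frame(result.model.full_table.round(10))
    if result.rocs:
        m["auc"] = {str(h): r.auc for h, r in result.rocs.items()}
    if result.cutoff is not None:
        m["cutoff"] = result.cutoff.cutoff
    if result.logrank is not None:
        m["logrank_chi2"], m["logrank_p"] = result.logrank
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.immune_lnc is not None:
        result.immune_lnc.to_csv(outdir / "immune_lncrna.tsv", sep="\t")
    if result.de_table is not None:
        result.de_table.to_csv(outdir / "de_table.tsv", sep="\t")
    if result.pairs is not None:
        result.pairs.one_fraction.rename("one_fraction").to_csv(outdir / "pairs.tsv", sep="\t")
        result.pairs.indicators.to_csv(outdir / "pair_indicators.tsv", sep="\t")
    if result.univariate is not None:
        result.univariate.to_csv(outdir / "cox_univariate.tsv", sep="\t")
    if result.lasso_freq is not None:
        result.lasso_freq.to_csv(outdir / "lasso_frequencies.tsv", sep="\t")
    if result.model is not None:
        result.model.full_table.to_csv(outdir / "model_full.tsv", sep="\t")
        result.model.to_frame().to_csv(outdir / "model.tsv", sep="\t")
    if result.scores is not None:
        result.scores.to_csv(outdir / "risk_scores.tsv", sep="\t")
    for h, roc in result.rocs.items():
        pd.DataFrame(
            {"threshold": roc.thresholds, "sensitivity": roc.sensitivity, "specificity": roc.specificity}
        ).to_csv(outdir / f"roc_{h}.tsv", sep="\t", index=False)
    if result.cutoff is not None:
        (outdir / "cutoff.json").write_text(json.dumps(dataclasses.asdict(result.cutoff), indent=2))
    if result.groups is not None:
        result.groups.to_csv(outdir / "km_groups.tsv", sep="\t")
    if result.clinical_cox is not None:
        uni, multi = result.clinical_cox
        uni.to_csv(outdir / "cox_clinical_univariate.tsv", sep="\t")
        multi.to_csv(outdir / "cox_clinical_multivariate.tsv", sep="\t")
    for name, df in [
        ("clinical_assoc", result.clinical_assoc),
        ("subgroup_tests", result.subgroup_tests),
        ("infiltration_corr", result.infiltration_corr),
        ("checkpoint_tests", result.checkpoint_tests),
        ("drug_tests", result.drug_tests),
    ]:
        if df is not None:
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
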