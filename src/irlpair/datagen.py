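"""Synthetic cohorts with planted effects for end-to-end testing.

The generator emulates the statistical structure the pipeline assumes:

* linear-scale non-negative expression, log-normal on the log2 scale,
  over tumor and normal samples, with lncRNA / protein-coding biotypes;
* a designated immune mRNA subset; a block of lncRNAs co-expressed with
  immune genes at a target Pearson correlation;
* differentially expressed lncRNAs shifted by ``de_log2fc`` on the log2
  scale in tumor samples (the log2 ratio of linear-scale group means
  equals the shift in expectation because the groups share a variance);
* survival times for tumor patients from an exponential proportional-
  hazards model whose log-hazard is the sum of planted per-pair log
  hazard ratios times the binary pair indicators, with independent
  exponential censoring tuned to the requested censoring fraction;
* ordinal clinical covariates (grade, stage, T, N, M) thresholded from
  the true linear predictor plus noise; age and gender independent;
* immune-infiltration and drug-IC50 tables in which designated columns
  have a planted monotone association with the true linear predictor.

Everything is deterministic given the seed. The planted truth is
returned alongside the data so that recovery can be measured.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from irlpair.io_formats import ExpressionMatrix, GeneAnnotation, SurvivalTable, NORMAL, TUMOR
from irlpair.pairing import canonical_pair, encode_pair, pair_id
from irlpair.association import CHECKPOINT_GENES

#: Standard deviation of log2 expression around each gene's mean.
LOG2_SD = 0.8


class ConfigError(ValueError):
    """An invalid simulation configuration, naming the offending field."""


@dataclass
class SimConfig:
    """Cohort geometry and planted effect sizes.

    The defaults describe the standard strong-effect study condition
    used throughout the test-bench: a 400-tumor / 50-normal cohort with
    three planted prognostic pairs of log hazard ratio 1.0.
    """

    n_tumor: int = 400
    n_normal: int = 50
    n_lncrna: int = 40
    n_mrna: int = 60
    n_immune_mrna: int = 20
    n_coexpressed_lnc: int = 12
    coexpression_r: float = 0.6
    n_de_lnc: int = 10
    de_log2fc: float = 2.0
    n_planted_pairs: int = 3
    planted_log_hr: float = 1.0
    baseline_hazard: float = 1.0 / 2000.0  # events per day
    censoring_rate: float = 0.3
    horizon_days: float = 1825.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lncrna", "n_mrna", "n_immune_mrna",
                     "n_coexpressed_lnc", "n_de_lnc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_planted_pairs < 0:
            raise ConfigError("n_planted_pairs must be non-negative")
        if not 0 <= self.censoring_rate <= 1:
            raise ConfigError("censoring_rate must lie in [0, 1]")
        if not 0 <= self.coexpression_r <= 1:
            raise ConfigError("coexpression_r must lie in [0, 1]")
        if self.n_immune_mrna > self.n_mrna:
            raise ConfigError("n_immune_mrna cannot exceed n_mrna")
        if self.n_coexpressed_lnc > self.n_lncrna:
            raise ConfigError("n_coexpressed_lnc cannot exceed n_lncrna")
        if self.n_de_lnc > self.n_coexpressed_lnc:
            raise ConfigError("n_de_lnc cannot exceed n_coexpressed_lnc")
        max_pairs = self.n_de_lnc * (self.n_de_lnc - 1) // 2
        if self.n_planted_pairs > max_pairs:
            raise ConfigError(f"n_planted_pairs exceeds C(n_de_lnc, 2) = {max_pairs}")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.horizon_days <= 0:
            raise ConfigError("horizon_days must be positive")


@dataclass
class PlantedTruth:
    de_lnc_ids: list[str]
    planted_pairs: list[tuple[str, str, float]]  # canonical orientation
    clinical_effect_map: dict[str, str]
    infiltration_effects: dict[str, str] = field(default_factory=dict)
    drug_effects: dict[str, str] = field(default_factory=dict)
    checkpoint_effects: dict[str, str] = field(default_factory=dict)
    linear_predictor: pd.Series | None = None  # true eta per tumor patient

    @property
    def planted_pair_ids(self) -> list[str]:
        return [pair_id(a, b) for a, b, _ in self.planted_pairs]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    annotation: GeneAnnotation
    immune_genes: set[str]
    survival: SurvivalTable
    infiltration: pd.DataFrame
    ic50: pd.DataFrame
    truth: PlantedTruth
    config: SimConfig


def _censoring_scale(lambdas: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c / (c + lambda_i) = target."""
    if target <= 0:
        return 0.0
    if target >= 1:
        return np.inf
    f = lambda c: np.mean(c / (c + lambdas)) - target
    hi = lambdas.max() * 1e6
    return brentq(f, 1e-15, hi)


def _ordinal_from_eta(rng, eta_std: np.ndarray, labels: list[str], noise_sd: float = 1.0) -> np.ndarray:
    """Threshold eta + noise into ordered categories at equal quantiles."""
    z = eta_std + rng.normal(0, noise_sd, size=len(eta_std))
    qs = np.quantile(z, np.linspace(0, 1, len(labels) + 1)[1:-1])
    return np.asarray(labels, dtype=object)[np.searchsorted(qs, z)]


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; bit-identical for a fixed config."""
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)

    lnc_ids = [f"LNC{i:04d}" for i in range(c.n_lncrna)]
    n_checkpoint = min(len(CHECKPOINT_GENES), c.n_immune_mrna)
    immune_ids = list(CHECKPOINT_GENES[:n_checkpoint]) + [
        f"IMM{i:04d}" for i in range(c.n_immune_mrna - n_checkpoint)
    ]
    other_mrna = [f"PCG{i:04d}" for i in range(c.n_mrna - c.n_immune_mrna)]
    mrna_ids = immune_ids + other_mrna
    tumor_ids = [f"T{i:04d}" for i in range(c.n_tumor)]
    normal_ids = [f"N{i:04d}" for i in range(c.n_normal)]
    samples = tumor_ids + normal_ids
    n_samples = len(samples)
    is_tumor = np.array([1.0] * c.n_tumor + [0.0] * c.n_normal)

    # --- mRNA log2 expression -------------------------------------------
    mrna_mu = rng.uniform(1.0, 6.0, size=c.n_mrna)
    mrna_log2 = mrna_mu[:, None] + LOG2_SD * rng.standard_normal((c.n_mrna, n_samples))
    mrna_df = pd.DataFrame(mrna_log2, index=mrna_ids, columns=samples)

    # immune partners for co-expressed lncRNAs: prefer non-checkpoint
    # immune genes so planted checkpoint shifts stay independent
    partners = [g for g in immune_ids if g not in CHECKPOINT_GENES] or immune_ids
    partner_resid = {
        g: (mrna_df.loc[g].to_numpy() - mrna_mu[mrna_ids.index(g)]) / LOG2_SD for g in partners
    }

    # --- lncRNA log2 expression -----------------------------------------
    de_ids = lnc_ids[: c.n_de_lnc]
    coexp_ids = lnc_ids[: c.n_coexpressed_lnc]
    # DE genes share one baseline so pair indicators are balanced
    lnc_log2 = np.empty((c.n_lncrna, n_samples))
    r = c.coexpression_r
    for i, g in enumerate(lnc_ids):
        mu = 3.0 if g in de_ids else rng.uniform(1.0, 6.0)
        eps = rng.standard_normal(n_samples)
        if g in coexp_ids:
            z = partner_resid[partners[i % len(partners)]]
            resid = r * z + np.sqrt(1 - r * r) * eps
        else:
            resid = eps
        shift = c.de_log2fc * is_tumor if g in de_ids else 0.0
        lnc_log2[i] = mu + shift + LOG2_SD * resid
    lnc_df = pd.DataFrame(lnc_log2, index=lnc_ids, columns=samples)

    # --- planted pairs and the true linear predictor --------------------
    if c.n_planted_pairs <= c.n_de_lnc // 2:
        raw_pairs = [(de_ids[2 * k], de_ids[2 * k + 1]) for k in range(c.n_planted_pairs)]
    else:
        raw_pairs = list(itertools.combinations(de_ids, 2))[: c.n_planted_pairs]
    planted = [(*canonical_pair(a, b), c.planted_log_hr) for a, b in raw_pairs]
    eta = np.zeros(c.n_tumor)
    for a, b, b_hr in planted:
        alpha = encode_pair(lnc_df.loc[a, tumor_ids], lnc_df.loc[b, tumor_ids])
        eta += b_hr * alpha.astype(float)
    eta_series = pd.Series(eta, index=tumor_ids, name="eta")
    eta_std = (eta - eta.mean()) / eta.std() if eta.std() > 0 else np.zeros_like(eta)

    # --- planted checkpoint-gene shifts (tumor samples only) ------------
    checkpoint_effects = {}
    if n_checkpoint >= 2 and eta.std() > 0:
        checkpoint_effects = {"CTLA4": "+", "CD274": "-"}
        for g, sign in checkpoint_effects.items():
            if g in mrna_df.index:
                delta = (1.0 if sign == "+" else -1.0) * 0.8 * eta_std
                mrna_df.loc[g, tumor_ids] = mrna_df.loc[g, tumor_ids].to_numpy() + delta

    expr_values = np.power(2.0, pd.concat([lnc_df, mrna_df]).to_numpy())
    expression = ExpressionMatrix(
        pd.DataFrame(expr_values, index=lnc_ids + mrna_ids, columns=samples),
        pd.Series([TUMOR] * c.n_tumor + [NORMAL] * c.n_normal, index=samples),
    )

    annotation = GeneAnnotation(
        pd.DataFrame(
            {"gene_name": lnc_ids + mrna_ids,
             "biotype": ["lncRNA"] * c.n_lncrna + ["protein_coding"] * c.n_mrna},
            index=pd.Index(lnc_ids + mrna_ids, name="gene_id"),
        )
    )

    # --- survival --------------------------------------------------------
    lam = c.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    cens_rate = _censoring_scale(lam, c.censoring_rate)
    if cens_rate > 0:
        t_cens = rng.exponential(1.0 / cens_rate, size=c.n_tumor)
    else:
        t_cens = np.full(c.n_tumor, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # keep times strictly positive

    grade = _ordinal_from_eta(rng, eta_std, ["G1", "G2", "G3", "G4"])
    stage = _ordinal_from_eta(rng, eta_std, ["I", "II", "III", "IV"])
    t_stage = _ordinal_from_eta(rng, eta_std, ["T1", "T2", "T3", "T4"])
    n_stage = _ordinal_from_eta(rng, eta_std, ["N0", "N1"])
    m_stage = _ordinal_from_eta(rng, eta_std, ["M0", "M1"])
    survival = SurvivalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "age": rng.integers(40, 86, size=c.n_tumor).astype(float),
                "gender": rng.choice(["female", "male"], size=c.n_tumor),
                "grade": grade,
                "stage": stage,
                "T": t_stage,
                "N": n_stage,
                "M": m_stage,
            },
            index=pd.Index(tumor_ids, name="patient_id"),
        )
    )
    clinical_effect_map = {"grade": "+", "stage": "+", "T": "+", "N": "+", "M": "+"}

    # --- infiltration scores (tumor samples) ----------------------------
    cell_types = [
        "NK_cells|XCELL", "T_reg|CIBERSORT", "Macrophage_M1|QUANTISEQ", "Neutrophil|TIMER",
        "B_cells|EPIC", "CD8_T|MCPCOUNTER", "Monocyte|CIBERSORT", "Mast_cells|XCELL",
        "Dendritic|QUANTISEQ", "CD4_T|TIMER",
    ]
    infiltration_effects = {"NK_cells|XCELL": "+", "T_reg|CIBERSORT": "+", "Neutrophil|TIMER": "-"}
    infil = {}
    for ct in cell_types:
        base = rng.normal(0, 1, size=c.n_tumor)
        sign = infiltration_effects.get(ct)
        if sign and eta.std() > 0:
            base = base + (0.8 if sign == "+" else -0.8) * eta_std
        infil[ct] = base
    infiltration = pd.DataFrame(infil, index=pd.Index(tumor_ids, name="sample_id"))

    # --- drug IC50 (tumor samples) --------------------------------------
    drugs = ["sunitinib", "axitinib", "bevacizumab", "pazopanib", "sorafenib"]
    drug_effects = {"sunitinib": "-"}  # lower IC50 (more sensitive) at high risk
    ic50_cols = {}
    for d in drugs:
        base = rng.normal(3.0, 0.6, size=c.n_tumor)
        if drug_effects.get(d) == "-" and eta.std() > 0:
            base = base - 0.8 * eta_std
        ic50_cols[d] = base
    ic50 = pd.DataFrame(ic50_cols, index=pd.Index(tumor_ids, name="sample_id"))

    truth = PlantedTruth(
        de_lnc_ids=de_ids,
        planted_pairs=planted,
        clinical_effect_map=clinical_effect_map,
        infiltration_effects=infiltration_effects,
        drug_effects=drug_effects,
        checkpoint_effects=checkpoint_effects,
        linear_predictor=eta_series,
    )
    return SyntheticCohort(expression, annotation, set(immune_ids), survival, infiltration, ic50, truth, c)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort in the same TSV formats the pipeline readers accept,
    so a simulated cohort is a drop-in fixture for file-based runs."""
    from pathlib import Path

    from irlpair.io_formats import write_annotation, write_expression, write_gene_list, write_score_table, write_survival

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, outdir / "expression.tsv", outdir / "sample_groups.tsv")
    write_annotation(cohort.annotation, outdir / "annotation.tsv")
    write_gene_list(cohort.immune_genes, outdir / "immune_genes.txt")
    write_survival(cohort.survival, outdir / "survival.tsv")
    write_score_table(cohort.infiltration, outdir / "infiltration.tsv")
    write_score_table(cohort.ic50, outdir / "ic50.tsv")
    truth = {
        "de_lnc_ids": cohort.truth.de_lnc_ids,
        "planted_pairs": [list(p) for p in cohort.truth.planted_pairs],
        "clinical_effect_map": cohort.truth.clinical_effect_map,
        "infiltration_effects": cohort.truth.infiltration_effects,
        "drug_effects": cohort.truth.drug_effects,
        "checkpoint_effects": cohort.truth.checkpoint_effects,
        "config": asdict(cohort.config),
    }
    import json

    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def planted_recovery_report(cohort: SyntheticCohort, model) -> dict:
    """How much of the planted signal a fitted risk model recovered.

    Returns the fraction of planted pairs present among the model's
    pairs and, over those recovered, the fraction whose coefficient sign
    matches the planted log hazard ratio.
    """
    planted = {pair_id(a, b): hr for a, b, hr in cohort.truth.planted_pairs}
    model_pairs = set(model.pair_ids)
    recovered = [p for p in planted if p in model_pairs]
    n_planted = len(planted)
    recovery = len(recovered) / n_planted if n_planted else float("nan")
    if recovered:
        coef = model.coefficients
        agree = np.mean([np.sign(coef[p]) == np.sign(planted[p]) for p in recovered])
        sign_agreement = float(agree)
    else:
        sign_agreement = float("nan")
    return {
        "n_planted": n_planted,
        "n_recovered": len(recovered),
        "recovery": recovery,
        "sign_agreement": sign_agreement,
        "recovered_pairs": recovered,
    }
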