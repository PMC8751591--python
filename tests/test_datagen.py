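import dataclasses

import numpy as np
import pandas as pd
import pytest

from irlpair.datagen import (
    ConfigError,
    SimConfig,
    generate_cohort,
    planted_recovery_report,
    write_cohort,
)
from irlpair.io_formats import read_annotation, read_expression, read_survival
from irlpair.pairing import encode_pair
from irlpair.survival_model import RiskModel, CoxRow


SMALL = SimConfig(n_tumor=150, n_normal=40, n_lncrna=20, n_mrna=30, n_immune_mrna=10,
                  n_coexpressed_lnc=8, n_de_lnc=6, n_planted_pairs=2, seed=0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("n_tumor", 0, "n_tumor"),
            ("censoring_rate", 1.3, "censoring_rate"),
            ("coexpression_r", -0.1, "coexpression_r"),
            ("n_de_lnc", 9, "n_de_lnc"),  # exceeds n_coexpressed_lnc = 8
            ("n_planted_pairs", 16, "n_planted_pairs"),  # > C(6, 2)
            ("baseline_hazard", 0.0, "baseline_hazard"),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value, match):
        cfg = dataclasses.replace(SMALL, **{field: value})
        with pytest.raises(ConfigError, match=match):
            generate_cohort(cfg)


class TestGeneration:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(SMALL)
        b = generate_cohort(SMALL)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.survival.data, b.survival.data)
        pd.testing.assert_frame_equal(a.infiltration, b.infiltration)
        pd.testing.assert_frame_equal(a.ic50, b.ic50)
        assert a.truth.planted_pairs == b.truth.planted_pairs

    def test_basic_invariants(self):
        c = generate_cohort(SMALL)
        assert (c.expression.values.to_numpy() >= 0).all()
        assert (c.survival.data["time"] > 0).all()
        assert set(c.survival.data["event"].unique()) <= {0, 1}
        planted_genes = {g for a, b, _ in c.truth.planted_pairs for g in (a, b)}
        assert planted_genes <= set(c.truth.de_lnc_ids)

    def test_null_effect_pairs_uncorrelated_with_times(self):
        cfg = dataclasses.replace(SMALL, n_tumor=500, planted_log_hr=0.0, censoring_rate=0.0)
        c = generate_cohort(cfg)
        assert (c.truth.linear_predictor == 0).all()
        a, b, _ = c.truth.planted_pairs[0]
        tum = c.expression.samples_in_group("tumor")
        alpha = encode_pair(c.expression.values.loc[a, tum], c.expression.values.loc[b, tum])
        r = np.corrcoef(alpha, c.survival.data["time"].to_numpy())[0, 1]
        assert abs(r) < 0.1

    def test_de_log2_ratio_matches_planted_fold_change(self):
        # Monte-Carlo over 20 seeds at 200 tumor + 40 normal
        cfg = dataclasses.replace(SMALL, n_tumor=200, n_normal=40, de_log2fc=2.0)
        ratios = []
        for seed in range(20):
            c = generate_cohort(dataclasses.replace(cfg, seed=seed))
            tum = c.expression.samples_in_group("tumor")
            nor = c.expression.samples_in_group("normal")
            for g in c.truth.de_lnc_ids:
                v = c.expression.values
                ratios.append(np.log2(v.loc[g, tum].mean() / v.loc[g, nor].mean()))
        ratios = np.asarray(ratios).reshape(20, -1)
        assert np.allclose(ratios.mean(axis=0), 2.0, atol=0.3)

    def test_coexpressed_lnc_hits_target_correlation(self):
        c = generate_cohort(SimConfig(seed=5))
        v = np.log2(c.expression.values + 1e-12)
        immune = [g for g in c.immune_genes if g.startswith("IMM")]
        # non-DE co-expressed lncRNAs carry the undiluted correlation
        pure = [g for g in [f"LNC{i:04d}" for i in range(10, 12)]]
        for g in pure:
            best = max(abs(np.corrcoef(v.loc[g], v.loc[h])[0, 1]) for h in immune)
            assert best == pytest.approx(0.6, abs=0.12)

    def test_censoring_rate_is_tuned(self):
        cfg = dataclasses.replace(SMALL, n_tumor=800, censoring_rate=0.4)
        c = generate_cohort(cfg)
        assert (1 - c.survival.data["event"].mean()) == pytest.approx(0.4, abs=0.07)
        c0 = generate_cohort(dataclasses.replace(SMALL, censoring_rate=0.0))
        assert (c0.survival.data["event"] == 1).all()

    def test_cox_recovers_planted_log_hr(self):
        # single planted pair, no censoring: the true log-HR falls inside
        # the univariate Cox 95% CI in the vast majority of replicates
        from lifelines import CoxPHFitter

        cfg = dataclasses.replace(SMALL, n_planted_pairs=1, planted_log_hr=0.8,
                                  censoring_rate=0.0, n_tumor=150)
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            c = generate_cohort(dataclasses.replace(cfg, seed=seed))
            a, b, b_true = c.truth.planted_pairs[0]
            tum = c.expression.samples_in_group("tumor")
            df = c.survival.data[["time", "event"]].copy()
            df["x"] = encode_pair(c.expression.values.loc[a, tum], c.expression.values.loc[b, tum])
            cph = CoxPHFitter().fit(df, "time", "event")
            lo, hi = cph.summary.loc["x", ["coef lower 95%", "coef upper 95%"]]
            hits += lo <= b_true <= hi
        assert hits >= 0.9 * n_rep


class TestRecoveryReport:
    def _model_from(self, pairs):
        rows = [CoxRow(p, coef, np.exp(coef), np.exp(coef) / 2, np.exp(coef) * 2, 0.001)
                for p, coef in pairs]
        return RiskModel(rows=rows, retention_rule="p < 0.05", training_samples=[])

    def test_exact_model_scores_one(self):
        c = generate_cohort(SMALL)
        model = self._model_from([(pid, 1.0) for pid in c.truth.planted_pair_ids])
        rep = planted_recovery_report(c, model)
        assert rep["recovery"] == 1.0 and rep["sign_agreement"] == 1.0

    def test_empty_model_scores_zero(self):
        c = generate_cohort(SMALL)
        rep = planted_recovery_report(c, self._model_from([]))
        assert rep["recovery"] == 0.0
        assert np.isnan(rep["sign_agreement"])

    def test_sign_disagreement_detected(self):
        c = generate_cohort(SMALL)
        model = self._model_from([(c.truth.planted_pair_ids[0], -1.0)])
        rep = planted_recovery_report(c, model)
        assert rep["recovery"] == pytest.approx(1 / 2)
        assert rep["sign_agreement"] == 0.0


def test_written_cohort_is_a_drop_in_fixture(tmp_path):
    c = generate_cohort(SMALL)
    write_cohort(c, tmp_path)
    expr = read_expression(tmp_path / "expression.tsv", tmp_path / "sample_groups.tsv")
    pd.testing.assert_frame_equal(expr.values, c.expression.values, check_names=False)
    ann = read_annotation(str(tmp_path / "annotation.tsv"))
    pd.testing.assert_frame_equal(ann.table, c.annotation.table)
    surv = read_survival(tmp_path / "survival.tsv")
    assert surv.patient_ids == c.survival.patient_ids
    assert np.array_equal(surv.data["time"], c.survival.data["time"])
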