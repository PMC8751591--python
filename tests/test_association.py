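import numpy as np
import pandas as pd
import pytest

from irlpair.association import (
    CHECKPOINT_GENES,
    checkpoint_expression_test,
    clinical_association,
    drug_sensitivity_test,
    infiltration_correlation,
    records_to_frame,
    score_subgroup_test,
)
from irlpair.io_formats import ExpressionMatrix


def groups_from(labels):
    return pd.Series(labels, index=[f"P{i}" for i in range(len(labels))], name="risk_group")


class TestClinicalAssociation:
    def _record(self, table):
        groups, covs = [], []
        for gi, row in enumerate(table):
            for li, count in enumerate(row):
                groups += [f"g{gi}"] * count
                covs += [f"l{li}"] * count
        g = groups_from(groups)
        c = pd.Series(covs, index=g.index, name="cov")
        return clinical_association(g, c)

    def test_independent_table_statistic_zero(self):
        rec = self._record([[10, 10], [10, 10]])
        assert rec.statistic == pytest.approx(0.0)
        assert rec.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        rec = self._record([[20, 0], [0, 20]])
        assert rec.p_value < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_statistic_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(3, 30, size=(2, 3))
        rec = self._record(table.tolist())
        obs = table.astype(float)
        expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        assert rec.statistic == pytest.approx(((obs - expected) ** 2 / expected).sum())

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            self._record([[10], [12]])


class TestScoreSubgroupTest:
    def test_one_observation_per_group_exact_p_one(self):
        scores = pd.Series([1.0, 2.0], index=["P0", "P1"])
        rec = score_subgroup_test(scores, groups_from(["a", "b"]))
        assert rec.method == "wilcoxon"
        assert rec.p_value == pytest.approx(1.0)

    def test_disjoint_ranges_minimal_exact_p(self):
        scores = pd.Series(np.r_[np.arange(10), np.arange(100, 110)].astype(float),
                           index=[f"P{i}" for i in range(20)])
        rec = score_subgroup_test(scores, groups_from(["a"] * 10 + ["b"] * 10))
        # most extreme two-sided exact p at 10 vs 10: 2 / C(20, 10)
        assert rec.p_value == pytest.approx(2 / 184756)

    def test_three_levels_use_kruskal(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.standard_normal(30), index=[f"P{i}" for i in range(30)])
        rec = score_subgroup_test(scores, groups_from(list("abc") * 10))
        assert rec.method == "kruskal"

    def test_label_permutation_null_is_calibrated(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            scores = pd.Series(rng.standard_normal(40), index=[f"P{i}" for i in range(40)])
            labels = groups_from(rng.permutation(["a"] * 20 + ["b"] * 20))
            ps.append(score_subgroup_test(scores, labels).p_value)
        assert np.mean(np.array(ps) < 0.05) < 0.25

    def test_single_level_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["P0", "P1"])
        with pytest.raises(ValueError):
            score_subgroup_test(scores, groups_from(["a", "a"]))


class TestInfiltrationCorrelation:
    def test_score_itself_has_r_one(self):
        rng = np.random.default_rng(1)
        idx = [f"P{i}" for i in range(40)]
        scores = pd.Series(rng.standard_normal(40), index=idx)
        table = pd.DataFrame({"self|TEST": scores, "noise|TEST": rng.standard_normal(40)}, index=idx)
        out = infiltration_correlation(scores, table)
        assert out.loc["self|TEST", "r"] == pytest.approx(1.0)
        assert bool(out.loc["self|TEST", "retained"])

    def test_zero_variance_column_skipped(self):
        idx = [f"P{i}" for i in range(20)]
        scores = pd.Series(np.random.default_rng(2).standard_normal(20), index=idx)
        table = pd.DataFrame({"flat|X": np.ones(20)}, index=idx)
        with pytest.warns(UserWarning, match="zero variance"):
            out = infiltration_correlation(scores, table)
        assert len(out) == 0

    def test_planted_directions_recovered(self, strong_cohort):
        eta = strong_cohort.truth.linear_predictor
        out = infiltration_correlation(eta, strong_cohort.infiltration)
        for col, sign in strong_cohort.truth.infiltration_effects.items():
            assert bool(out.loc[col, "retained"])
            assert np.sign(out.loc[col, "r"]) == (1 if sign == "+" else -1)

    def test_null_columns_rarely_retained(self):
        rng = np.random.default_rng(3)
        idx = [f"P{i}" for i in range(300)]
        scores = pd.Series(rng.standard_normal(300), index=idx)
        table = pd.DataFrame(rng.standard_normal((300, 30)),
                             index=idx, columns=[f"ct{i}|M" for i in range(30)])
        out = infiltration_correlation(scores, table)
        # expect about 0.05 * 30 = 1.5 retained
        assert out["retained"].sum() <= 6


class TestCheckpointTest:
    def test_missing_gene_reported(self):
        values = pd.DataFrame(
            np.random.default_rng(4).lognormal(size=(1, 10)), index=["CTLA4"],
            columns=[f"P{i}" for i in range(10)],
        )
        expr = ExpressionMatrix(values, pd.Series("tumor", index=values.columns))
        groups = groups_from(["high"] * 5 + ["low"] * 5)
        records, missing = checkpoint_expression_test(expr, groups)
        assert [r.variable for r in records] == ["CTLA4"]
        assert set(missing) == set(CHECKPOINT_GENES) - {"CTLA4"}

    def test_gene_alias_resolved(self):
        values = pd.DataFrame(
            np.random.default_rng(5).lognormal(size=(1, 10)), index=["GAL9"],
            columns=[f"P{i}" for i in range(10)],
        )
        expr = ExpressionMatrix(values, pd.Series("tumor", index=values.columns))
        records, missing = checkpoint_expression_test(expr, groups_from(["high"] * 5 + ["low"] * 5))
        assert "LGALS9" not in missing

    def test_planted_shifts_recovered(self, strong_cohort):
        eta = strong_cohort.truth.linear_predictor
        groups = pd.Series(np.where(eta > eta.median(), "high", "low"), index=eta.index)
        records, _ = checkpoint_expression_test(strong_cohort.expression, groups)
        by_gene = {r.variable: r for r in records}
        for gene, sign in strong_cohort.truth.checkpoint_effects.items():
            assert by_gene[gene].p_value < 0.01
            assert np.sign(by_gene[gene].estimate) == (1 if sign == "+" else -1)


class TestDrugSensitivity:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(6)
        idx = [f"P{i}" for i in range(60)]
        ic50 = pd.DataFrame({"drugA": rng.normal(3, 0.5, 60)}, index=idx)
        groups = pd.Series(rng.permutation(["high"] * 30 + ["low"] * 30), index=idx)
        recs = drug_sensitivity_test(ic50, groups)
        assert recs[0].p_value > 0.01

    def test_planted_drug_flagged_with_direction(self, strong_cohort):
        eta = strong_cohort.truth.linear_predictor
        groups = pd.Series(np.where(eta > eta.median(), "high", "low"), index=eta.index)
        recs = drug_sensitivity_test(strong_cohort.ic50, groups)
        frame = records_to_frame(recs)
        assert frame.loc["sunitinib", "p_value"] < 0.001
        assert frame.loc["sunitinib", "estimate"] < 0  # lower IC50 in high risk
        others = frame.drop("sunitinib")
        assert (others["p_value"] > 0.001).all()

    def test_tiny_group_is_an_error(self):
        idx = [f"P{i}" for i in range(5)]
        ic50 = pd.DataFrame({"drugA": np.arange(5.0)}, index=idx)
        groups = pd.Series(["high"] * 4 + ["low"], index=idx)
        with pytest.raises(ValueError, match="drugA"):
            drug_sensitivity_test(ic50, groups)
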