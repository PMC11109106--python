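"""Unit tests for the spreading statistics and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

from conftest import TABLE1, TABLE2_GROUPS
from ecaspread import assessment as A
from ecaspread import eca_engine as E
from ecaspread import synthetic_data as SD
from ecaspread.rule_learning import RuleDistribution


class TestSpreadingIntensity:
    def test_worked_example(self):
        dist = RuleDistribution(probs={204: 0.845, 206: 0.085, 220: 0.07})
        si = A.spreading_intensity(dist, {204: 1.00, 206: 3.23, 220: 3.22})
        assert si == pytest.approx(1.34495, abs=1e-12)

    def test_identity_only_distribution_scores_one(self):
        assert A.spreading_intensity(RuleDistribution(probs={204: 1.0}), {204: 1.0}) == 1.0

    def test_uniform_mixture_is_arithmetic_mean(self):
        dist = RuleDistribution(probs={206: 0.5, 220: 0.5})
        assert A.spreading_intensity(dist, {206: 3.23, 220: 3.22}) == pytest.approx(3.225)

    def test_accepts_per_rule_intensity_records(self):
        pri = E.PerRuleIntensity(rule=204, mean_presence=100.0, intensity=1.0, convergent_mean=100.0)
        assert A.spreading_intensity(RuleDistribution(probs={204: 1.0}), {204: pri}) == 1.0

    def test_missing_rule_intensity_rejected(self):
        dist = RuleDistribution(probs={204: 0.5, 206: 0.5})
        with pytest.raises(KeyError, match="206"):
            A.spreading_intensity(dist, {204: 1.0})


class TestSpreadingAssessment:
    @pytest.mark.parametrize("cid, si, hs, sa", [(r[0], r[2], r[3], r[4]) for r in TABLE1])
    def test_reproduces_published_sa_column(self, cid, si, hs, sa):
        # 2.5e-9: the published table rounds SA in its last printed digit
        assert A.spreading_assessment(si, hs) == pytest.approx(sa, abs=2.5e-9)

    def test_neutral_weight(self):
        assert A.spreading_assessment(3.25, 1.0) == 3.25

    def test_out_of_range_hs_rejected_or_warns(self):
        with pytest.raises(ValueError):
            A.spreading_assessment(1.0, 1.5)
        with pytest.warns(UserWarning):
            A.spreading_assessment(1.0, 1.5, strict=False)

    def test_negative_si_rejected(self):
        with pytest.raises(ValueError):
            A.spreading_assessment(-0.1, 0.5)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "sa, group",
        [(2.395879991, "I"), (1.414210085, "III"), (0.740367631, "IV"), (1.96932607, "II")],
    )
    def test_published_examples(self, sa, group):
        assert A.classify_group(sa).value == group

    @pytest.mark.parametrize("sa, group", [(1.0, "IV"), (1.5, "III"), (2.0, "II")])
    def test_boundaries_go_to_lower_group(self, sa, group):
        assert A.classify_group(sa).value == group

    def test_negative_sa_rejected(self):
        with pytest.raises(ValueError):
            A.classify_group(-0.5)

    def test_full_published_grouping_reproduced(self):
        for cid, _n, _si, _hs, sa, _lon, _lat in TABLE1:
            expected = next(g for g, ids in TABLE2_GROUPS.items() if cid in ids)
            assert A.classify_group(sa).value == expected


class TestCollinearityFilter:
    @staticmethod
    def _corr(names, entries):
        m = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, r in entries:
            m.loc[a, b] = m.loc[b, a] = r
        return m

    def test_two_correlated_variables_keep_one(self):
        corr = self._corr(["a", "b"], [("a", "b", 0.9)])
        assert len(A.collinearity_filter(corr)) == 1

    def test_all_below_threshold_all_retained(self):
        corr = self._corr(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", -0.7)])
        assert A.collinearity_filter(corr) == ["a", "b", "c"]

    def test_greedy_drop_of_most_collinear_variable(self):
        # v1 correlates 0.95 with v2 and 0.85 with v3; dropping v1 resolves
        # every violation, so v2, v3, v4 survive
        corr = self._corr(
            ["v1", "v2", "v3", "v4"],
            [("v1", "v2", 0.95), ("v1", "v3", 0.85), ("v2", "v3", 0.3),
             ("v2", "v4", 0.2), ("v1", "v4", 0.5), ("v3", "v4", 0.1)],
        )
        assert A.collinearity_filter(corr, threshold=0.80) == ["v2", "v3", "v4"]

    def test_asymmetric_matrix_rejected(self):
        corr = self._corr(["a", "b"], [("a", "b", 0.5)])
        corr.iloc[0, 1] = 0.6
        with pytest.raises(ValueError, match="symmetric"):
            A.collinearity_filter(corr)


class TestRunPipeline:
    @pytest.fixture()
    def small_run(self, trained_classifier, rule_intensities):
        clf, _acc, _corpus = trained_classifier
        cfg = SD.SyntheticConfig(n_clusters=4, points_per_cluster=(40, 120), seed=3)
        occ, _ = SD.generate_occurrences(cfg)
        hs = SD.generate_hs_table(range(1, 5), seed=3)
        table, groups = A.run_pipeline(
            occ, hs, clf,
            A.PipelineConfig(k=4, seed=0),
            intensities=rule_intensities,
        )
        return occ, hs, table, groups

    def test_one_record_per_cluster(self, small_run):
        _occ, _hs, table, _groups = small_run
        assert table["cluster_id"].tolist() == [1, 2, 3, 4]

    def test_sa_audit_on_every_emitted_row(self, small_run):
        _occ, _hs, table, _groups = small_run
        assert np.allclose(table["sa"], table["si"] * table["hs"], rtol=1e-12)

    def test_groups_partition_the_clusters(self, small_run):
        _occ, _hs, table, groups = small_run
        listed = [c for cell in groups["clusters"] for c in cell.split(", ") if c]
        assert sorted(int(c) for c in listed) == table["cluster_id"].tolist()

    def test_group_column_matches_classify_rule(self, small_run):
        _occ, _hs, table, _groups = small_run
        for _, row in table.iterrows():
            assert row["group"] == A.classify_group(row["sa"]).value

    def test_n_presence_bounded_by_grid_and_points(self, small_run):
        occ, _hs, table, _groups = small_run
        assert (table["n_presence"] >= 1).all()
        assert (table["n_presence"] <= 400).all()
        assert table["n_presence"].sum() <= len(occ)

    def test_missing_hs_id_reported(self, trained_classifier, rule_intensities):
        clf, _acc, _corpus = trained_classifier
        cfg = SD.SyntheticConfig(n_clusters=3, points_per_cluster=30, seed=1)
        occ, _ = SD.generate_occurrences(cfg)
        hs = SD.generate_hs_table([1, 2], seed=0)  # id 3 missing
        with pytest.raises(ValueError, match=r"\[3\]"):
            A.run_pipeline(occ, hs, clf, A.PipelineConfig(k=3), intensities=rule_intensities)
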