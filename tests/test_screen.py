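"""Matrix screening: scoring, permutation p-values, overlaps, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from bcd import (PlantedConfound, PlantedSubtype, empirical_pvalues,
                 fence_diagnostics, filter_samples, generate_fixture,
                 histogram_counts, overlap_report, score_all, top_fraction)
from bcd.errors import BCDError
from bcd.screen import AnalyteScores
from .conftest import make_matrix


@pytest.fixture(scope="module")
def planted_matrix():
    return generate_fixture(
        n_analytes=20, n_cases=80, n_controls=90,
        planted=[PlantedSubtype(analyte_index=3, fraction=0.3)],
        confounded=[PlantedConfound(analyte_index=5)],
        seed=12)


@pytest.fixture(scope="module")
def planted_scores(planted_matrix):
    return score_all(planted_matrix)


class TestScoreAll:
    def test_subtype_analyte_outranks_noise(self, planted_scores):
        table = planted_scores.table
        null_ids = table.index.difference(["A0003", "A0005"])
        assert table.loc["A0003", "bcd"] > table.loc[null_ids, "bcd"].max()

    def test_constant_analyte_skipped_with_reason(self):
        values = np.vstack([np.full(10, 2.0),
                            np.arange(10, dtype=float)])
        m = make_matrix(values, labels=["case"] * 5 + ["control"] * 5)
        scores = score_all(m)
        assert "g0" in scores.skipped
        assert "g1" in scores.table.index

    def test_missing_values_dropped_not_fatal(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(2, 20))
        values[0, :3] = np.nan
        m = make_matrix(values, labels=["case"] * 10 + ["control"] * 10)
        scores = score_all(m)
        assert len(scores.table) == 2

    def test_too_few_group_values_skipped(self):
        values = np.random.default_rng(1).normal(size=(1, 10))
        m = make_matrix(values, labels=["case"] * 3 + ["control"] * 7)
        with pytest.raises(BCDError):
            score_all(m)  # the only analyte is skipped -> nothing scored

    def test_row_order_does_not_change_scores(self, planted_matrix,
                                              planted_scores):
        shuffled = planted_matrix.subset_analytes(
            list(planted_matrix.analyte_ids[::-1]))
        reshuffled = score_all(shuffled)
        merged = planted_scores.table.join(
            reshuffled.table, how="inner", lsuffix="", rsuffix="_r")
        for metric in ("bcd", "log2fc", "auc"):
            assert np.array_equal(merged[metric], merged[f"{metric}_r"])

    def test_ranks_are_a_permutation(self, planted_scores):
        n = len(planted_scores.table)
        for metric in ("bcd", "log2fc", "auc"):
            ranks = sorted(planted_scores.table[f"rank_{metric}"])
            assert ranks == list(range(1, n + 1))


class TestEmpiricalPvalues:
    def test_planted_analyte_gets_smallest_p(self, planted_matrix,
                                             planted_scores):
        scores = empirical_pvalues(planted_matrix, planted_scores,
                                   n_permutations=39, seed=5)
        table = scores.table
        assert table["p_bcd"].idxmin() == "A0003"
        assert ((table[["p_bcd", "p_fc", "p_auc"]] > 0).all().all()
                and (table[["p_bcd", "p_fc", "p_auc"]] <= 1).all().all())
        assert set(scores.cutoffs) == {"bcd", "log2fc", "auc"}

    def test_label_symmetric_analytes_are_unremarkable(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(30, 40)),
                        labels=["case"] * 20 + ["control"] * 20)
        scores = empirical_pvalues(m, score_all(m), n_permutations=49,
                                   seed=1)
        med = scores.table["p_bcd"].median()
        assert 0.25 < med < 0.75

    def test_requires_enough_permutations(self, planted_matrix,
                                          planted_scores):
        with pytest.raises(BCDError):
            empirical_pvalues(planted_matrix, planted_scores,
                              n_permutations=5)


class TestTopFractionAndOverlap:
    def _scores(self, values):
        table = pd.DataFrame({"bcd": values},
                             index=[f"g{i}" for i in range(len(values))])
        table["rank_bcd"] = table["bcd"].rank(
            ascending=False, method="first").astype(int)
        return AnalyteScores(table=table)

    def test_ceiling_count(self, planted_scores):
        assert len(top_fraction(planted_scores, "bcd", 0.05)) == 1
        assert len(top_fraction(planted_scores, "bcd", 1.0)) == 20
        assert len(top_fraction(planted_scores, "bcd", 0.26)) == 6

    def test_top_set_contains_largest(self, planted_scores):
        top = top_fraction(planted_scores, "bcd", 0.1)
        assert planted_scores.table["bcd"].idxmax() in top

    def test_invalid_arguments(self, planted_scores):
        with pytest.raises(BCDError):
            top_fraction(planted_scores, "bcd", 0.0)
        with pytest.raises(BCDError):
            top_fraction(planted_scores, "p_bcd", 0.05)

    def test_overlap_half(self):
        rep = overlap_report({"x": {"a", "b", "c", "d"},
                              "y": {"a", "b", "p", "q"}})
        assert rep["pairwise"]["x&y"]["pct_of_first"] == 50.0
        assert rep["all"]["intersection"] == 2

    def test_overlap_identical_and_disjoint(self):
        rep = overlap_report({"x": {"a", "b"}, "y": {"a", "b"}})
        assert rep["pairwise"]["x&y"]["pct_of_first"] == 100.0
        rep = overlap_report({"x": {"a"}, "y": {"b"}, "z": {"c"}})
        assert all(v["pct_of_first"] == 0.0
                   for v in rep["pairwise"].values())
        assert rep["all"]["intersection"] == 0

    def test_empty_set_rejected(self):
        with pytest.raises(BCDError):
            overlap_report({"x": set(), "y": {"a"}})


class TestFenceDiagnostics:
    def test_confounded_analyte_flags_level(self, planted_matrix,
                                            planted_scores):
        rep = fence_diagnostics(planted_matrix, planted_scores,
                                "A0005", "region")
        case_rows = rep.crosstab[rep.crosstab["group"] == "case"]
        top = case_rows.sort_values("count", ascending=False).iloc[0]
        assert top["level"] == 4
        assert top["proportion"] >= 0.9
        assert top["enriched"]
        assert 4 in rep.enriched_levels.get("case", [])

    def test_proportions_sum_to_one_per_group(self, planted_matrix,
                                              planted_scores):
        rep = fence_diagnostics(planted_matrix, planted_scores,
                                "A0005", "region")
        for _, sub in rep.crosstab.groupby("group"):
            assert sub["proportion"].sum() == pytest.approx(1.0)

    def test_no_clamps_gives_empty_report(self, planted_matrix,
                                          planted_scores):
        clean = planted_scores.table.index.difference(
            ["A0003", "A0005"])[0]
        rep = fence_diagnostics(planted_matrix, planted_scores,
                                clean, "region")
        if rep.n_clamped_cases == rep.n_clamped_controls == 0:
            assert rep.crosstab.empty
            assert rep.enriched_levels == {}

    def test_unknown_analyte_or_covariate(self, planted_matrix,
                                          planted_scores):
        with pytest.raises(BCDError):
            fence_diagnostics(planted_matrix, planted_scores,
                              "nope", "region")
        with pytest.raises(BCDError):
            fence_diagnostics(planted_matrix, planted_scores,
                              "A0005", "age")


class TestStratumRemovalInvariance:
    def test_scores_stable_for_stratum_identical_analytes(self):
        # two strata with identical case and control value patterns:
        # removing one stratum must leave AUC and FC exactly unchanged
        # (BCD moves only through its explicit n-correction)
        rng = np.random.default_rng(6)
        case_block = rng.normal(0.2, 0.05, 20)
        control_block = rng.normal(0.1, 0.05, 20)
        values = np.concatenate([case_block, case_block,
                                 control_block, control_block])
        m = make_matrix([values],
                        labels=["case"] * 40 + ["control"] * 40,
                        covariates={"region": [1] * 20 + [2] * 20
                                    + [1] * 20 + [2] * 20})
        full = score_all(m).table.iloc[0]
        half = score_all(filter_samples(m, "region", {2})).table.iloc[0]
        assert half["auc"] == pytest.approx(full["auc"], abs=1e-12)
        assert half["log2fc"] == pytest.approx(full["log2fc"], abs=1e-12)
        assert half["bcd"] == pytest.approx(full["bcd"], abs=0.01)


class TestHistogramCounts:
    def test_counts_partition_samples(self, planted_matrix):
        h = histogram_counts(planted_matrix, "A0003", n_bins=15)
        assert h["cases"].sum() == planted_matrix.n_cases
        assert h["controls"].sum() == planted_matrix.n_controls
        assert (h["bin_right"] > h["bin_left"]).all()
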