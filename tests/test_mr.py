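import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_matrix
from coexrank import (
    AnalysisError,
    ConfigError,
    CorrelationProfile,
    ExpressionMatrix,
    compound_reference,
    correlation_profile,
    mutual_rank,
    pairwise_mr_table,
    pcc,
    rank_profile,
    targeted_mr_table,
    top_candidates,
)
from oracle import brute_force_mr_matrix


class TestPcc:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_correlations(self, x, y, expected):
        assert pcc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_yields_undefined_marker(self):
        assert math.isnan(pcc([1, 2, 3, 4], [5, 5, 5, 5]))

    def test_length_mismatch_and_short_vectors_rejected(self):
        with pytest.raises(AnalysisError):
            pcc([1, 2, 3], [1, 2])
        with pytest.raises(AnalysisError):
            pcc([1, 2], [3, 4])


class TestRankProfile:
    def test_descending_pcc_gets_rank_one(self):
        profile = CorrelationProfile("r", pd.Series({"b": 1.0, "c": 0.8, "d": -1.0}))
        assert rank_profile(profile).to_dict() == {"b": 1.0, "c": 2.0, "d": 3.0}

    def test_ties_get_average_ranks(self):
        profile = CorrelationProfile("r", pd.Series({"a": 0.8, "b": 0.8, "c": -0.8}))
        assert rank_profile(profile).to_dict() == {"a": 1.5, "b": 1.5, "c": 3.0}

    def test_undefined_correlations_receive_no_rank(self):
        profile = CorrelationProfile("r", pd.Series({"a": 0.5, "b": np.nan}))
        ranks = rank_profile(profile)
        assert ranks.to_dict() == {"a": 1.0}

    def test_profile_without_defined_values_is_error(self):
        with pytest.raises(AnalysisError):
            rank_profile(CorrelationProfile("r", pd.Series({"a": np.nan})))


class TestMutualRank:
    def test_reciprocal_best_pair_has_mr_one(self, toy_matrix):
        v = mutual_rank(toy_matrix, "g1", "g2")
        assert (v.rank_ab, v.rank_ba, v.mr) == (1.0, 1.0, 1.0)

    def test_tied_profile_gives_fractional_rank(self, toy_matrix):
        v = mutual_rank(toy_matrix, "g1", "g4")
        assert (v.rank_ab, v.rank_ba) == (2.0, 1.5)
        assert v.mr == pytest.approx(math.sqrt(3.0), abs=1e-12)

    def test_symmetry_in_arguments(self, toy_matrix):
        assert mutual_rank(toy_matrix, "g2", "g1").mr == mutual_rank(toy_matrix, "g1", "g2").mr

    def test_absent_and_zero_variance_genes_rejected(self, toy_matrix):
        with pytest.raises(AnalysisError):
            mutual_rank(toy_matrix, "g1", "gX")
        flat = toy_matrix.with_row("flat", [7, 7, 7, 7])
        with pytest.raises(AnalysisError, match="flat"):
            mutual_rank(flat, "g1", "flat")


class TestTopCandidates:
    def test_highest_signed_pcc_first(self, toy_matrix):
        assert list(top_candidates(toy_matrix, "g1", 2).index) == ["g2", "g4"]

    def test_request_beyond_universe_returns_all(self, toy_matrix):
        assert len(top_candidates(toy_matrix, "g1", 10)) == 3

    def test_cap_clamps_with_warning(self, toy_matrix, caplog):
        top_candidates(toy_matrix, "g1", 5000)
        assert any("clamping" in m for m in caplog.messages)

    def test_zero_variance_reference_rejected(self, toy_matrix):
        flat = toy_matrix.with_row("flat", [1, 1, 1, 1])
        with pytest.raises(AnalysisError, match="flat"):
            top_candidates(flat, "flat", 2)


class TestTargetedTable:
    def test_toy_matrix_matches_hand_derivation(self, toy_matrix):
        table = targeted_mr_table(toy_matrix, "g1", 3)
        frame = table.frame[~table.frame["is_self"]].set_index("gene")
        assert frame.loc["g2", "mr"] == pytest.approx(1.0)
        assert frame.loc["g4", "mr"] == pytest.approx(math.sqrt(3.0))
        assert frame.loc["g3", "mr"] == pytest.approx(math.sqrt(7.5))
        assert list(frame.index) == ["g2", "g4", "g3"]  # ascending MR

    def test_self_row_is_first_and_marked(self, toy_matrix):
        table = targeted_mr_table(toy_matrix, "g1", 3)
        assert table.frame.iloc[0]["gene"] == "g1"
        assert bool(table.frame.iloc[0]["is_self"])
        assert table.to_frame().iloc[0]["mr"] == "self"

    def test_single_candidate_table(self, toy_matrix):
        assert len(targeted_mr_table(toy_matrix, "g1", 1)) == 1

    def test_agrees_with_brute_force_oracle_including_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n_genes = int(rng.integers(5, 30))
            matrix = random_matrix(rng, n_genes, int(rng.integers(6, 15)))
            oracle = brute_force_mr_matrix(matrix.data)
            reference = matrix.gene_ids[int(rng.integers(n_genes))]
            table = targeted_mr_table(matrix, reference, n_genes)
            for _, row in table.frame[~table.frame["is_self"]].iterrows():
                assert row["mr"] == pytest.approx(oracle.loc[reference, row["gene"]], abs=1e-9)

    def test_mr_bounds_and_rank_sandwich(self, planted):
        matrix, _ = planted
        table = targeted_mr_table(matrix, "G00001", 50)
        rows = table.frame[~table.frame["is_self"]]
        g = matrix.n_genes
        assert ((rows["mr"] >= 1.0) & (rows["mr"] <= g - 1)).all()
        lo = rows[["rank_ab", "rank_ba"]].min(axis=1)
        hi = rows[["rank_ab", "rank_ba"]].max(axis=1)
        assert ((rows["mr"] >= lo - 1e-12) & (rows["mr"] <= hi + 1e-12)).all()

    def test_planted_module_members_dominate_lowest_mrs(self, planted):
        matrix, truth = planted
        members = set(truth.loc[truth["module_id"] == "M1", "gene"])
        table = targeted_mr_table(matrix, "G00001", 20)
        assert (members - {"G00001"}) <= set(table.candidate_genes)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(min_value=0.1, max_value=10.0, allow_nan=False),
        beta=st.floats(min_value=-5.0, max_value=5.0, allow_nan=False),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_affine_transform_leaves_mrs_unchanged(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, 12, 8, with_ties=False)
        scaled = ExpressionMatrix(matrix.data * alpha + beta)
        a = targeted_mr_table(matrix, matrix.gene_ids[0], 11).frame
        b = targeted_mr_table(scaled, matrix.gene_ids[0], 11).frame
        assert list(a["gene"]) == list(b["gene"])
        np.testing.assert_allclose(a["mr"].to_numpy(), b["mr"].to_numpy(), equal_nan=True)


class TestPairwiseTable:
    def test_symmetric_matrix_with_self_diagonal(self, toy_matrix):
        table, matrix = pairwise_mr_table(toy_matrix, ["g1", "g2", "g4"])
        assert matrix.shape == (3, 3)
        assert np.isnan(np.diag(matrix.to_numpy())).all()
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(matrix.to_numpy()[off], matrix.to_numpy().T[off])
        assert matrix.loc["g1", "g2"] == pytest.approx(1.0)
        assert table.frame.iloc[0]["gene"] == "g1"

    def test_rows_keyed_to_first_gene_in_input_order(self, toy_matrix):
        table, _ = pairwise_mr_table(toy_matrix, ["g4", "g1", "g3"])
        assert table.reference == "g4"
        assert table.genes == ["g4", "g1", "g3"]

    def test_absent_genes_dropped_with_warning(self, toy_matrix, caplog):
        _, matrix = pairwise_mr_table(toy_matrix, ["g1", "gX", "g2"])
        assert list(matrix.index) == ["g1", "g2"]
        assert any("gX" in m for m in caplog.messages)

    def test_fewer_than_two_retained_is_error_listing_dropped(self, toy_matrix):
        with pytest.raises(AnalysisError, match="gX"):
            pairwise_mr_table(toy_matrix, ["g1", "gX"])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        matrix = random_matrix(rng, 20, 10)
        genes = matrix.gene_ids[:6]
        _, mr = pairwise_mr_table(matrix, genes)
        oracle = brute_force_mr_matrix(matrix.data)
        for a in genes:
            for b in genes:
                if a != b:
                    assert mr.loc[a, b] == pytest.approx(oracle.loc[a, b], abs=1e-9)


class TestCompoundReference:
    def test_average_sum_max_min(self, toy_matrix):
        avg = compound_reference(toy_matrix, ["g1", "g2"], "average", "c")
        assert avg.expression("c").tolist() == [1.5, 3.0, 4.5, 6.0]
        mx = compound_reference(toy_matrix, ["g1", "g3"], "maximum", "c")
        assert mx.expression("c").tolist() == [4.0, 3.0, 3.0, 4.0]

    def test_zero_variance_aggregate_rejected_before_mr(self, toy_matrix):
        with pytest.raises(AnalysisError, match="zero variance"):
            compound_reference(toy_matrix, ["g1", "g3"], "sum", "c")

    def test_label_collision_and_unknown_method(self, toy_matrix):
        with pytest.raises(Exception, match="g1"):
            compound_reference(toy_matrix, ["g1", "g2"], "average", "g1")
        with pytest.raises(ConfigError, match="median"):
            compound_reference(toy_matrix, ["g1", "g2"], "median", "c")

    def test_sum_and_average_give_identical_mr_tables(self, planted):
        matrix, truth = planted
        genes = list(truth.loc[truth["module_id"] == "M1", "gene"])[:4]
        t_sum = targeted_mr_table(
            compound_reference(matrix, genes, "sum", "agg"), "agg", 15
        ).frame
        t_avg = targeted_mr_table(
            compound_reference(matrix, genes, "average", "agg"), "agg", 15
        ).frame
        assert list(t_sum["gene"]) == list(t_avg["gene"])
        np.testing.assert_allclose(
            t_sum["mr"].to_numpy(), t_avg["mr"].to_numpy(), equal_nan=True
        )

    def test_compound_row_joins_the_rank_universe(self, toy_matrix):
        extended = compound_reference(toy_matrix, ["g1", "g4"], "average", "c")
        profile = correlation_profile(extended, "g2").correlations
        assert "c" in profile.index
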