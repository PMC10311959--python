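import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speedirt import (
    ResponseMatrix,
    build_covariates,
    code_missingness,
    cohens_d,
    cronbach_alpha,
    generate_dataset,
    read_response_matrix,
    summarize_descriptives,
    SimulationScenario,
)
from speedirt.data_io import design_matrix

M = np.nan


# ---------------------------------------------------------------- reading

class TestReadResponseMatrix:
    def test_parses_small_file(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("i1,i2\n1,0\n1,NA\nNA,NA\n")
        resp = read_response_matrix(p)
        assert resp.values.shape == (3, 2)
        assert resp.item_order == ["i1", "i2"]
        assert int(np.isnan(resp.values).sum()) == 3

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("i1,i2\n")
        with pytest.raises(ValueError, match="empty"):
            read_response_matrix(p)

    def test_unparseable_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("i1,i2\n1,0\n2,1\n")
        with pytest.raises(ValueError, match=r"row 2.*i1"):
            read_response_matrix(p)

    def test_duplicate_person_id_errors(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("person_id,i1\na,1\na,0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_response_matrix(p)

    def test_declared_missing_token(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("i1,i2\n1,9\n9,9\n")
        resp = read_response_matrix(p, missing_token="9")
        assert int(np.isnan(resp.values).sum()) == 3

    def test_round_trip_with_simulator_dimensions(self, tmp_path):
        data = generate_dataset(SimulationScenario(N=794, K=25, seed=5))
        paths = data.write(tmp_path)
        resp = read_response_matrix(paths["responses"])
        assert resp.values.shape == (794, 25)
        np.testing.assert_array_equal(
            np.isnan(resp.values), np.isnan(data.responses.values))


# ---------------------------------------------------------------- coding

class TestCodeMissingness:
    @pytest.mark.parametrize("row,expected", [
        ([1, 0, 1, 0, 1, 1], [1, 1, 1, 1, 1, 1]),
        ([M, M, M, M, M, M], [0, M, M, M, M, M]),
        ([1, 0, M, 1, M, M], [1, 1, 1, 1, 0, M]),
        ([1, 1, 1, 1, 1, M], [1, 1, 1, 1, 1, 0]),
    ])
    def test_fixture_rows(self, row, expected):
        resp = ResponseMatrix(np.array([row], dtype=float))
        got = code_missingness(resp).values[0]
        np.testing.assert_array_equal(got, np.array(expected, dtype=float))

    def test_idempotent_in_effect(self, toy_response):
        a = code_missingness(toy_response).values
        b = code_missingness(toy_response).values
        np.testing.assert_array_equal(a, b)

    def test_struct_missing_count_matches_zero_position(self, toy_response):
        ind = code_missingness(toy_response).values
        k = ind.shape[1]
        for row in ind:
            zeros = np.flatnonzero(row == 0.0)
            n_sm = int(np.isnan(row).sum())
            if zeros.size:
                assert n_sm == k - (zeros[0] + 1)
            else:
                assert n_sm == 0

    def test_fully_observed_matrix_is_all_ones(self):
        resp = ResponseMatrix(np.ones((4, 3)))
        assert (code_missingness(resp).values == 1.0).all()

    @given(st.lists(st.sampled_from([0.0, 1.0, M]), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_row_invariants_hold_for_any_row(self, cells):
        resp = ResponseMatrix(np.array([cells], dtype=float))
        row = code_missingness(resp).values[0]
        zeros = np.flatnonzero(row == 0.0)
        assert zeros.size <= 1
        assert (row == 1.0).sum() <= len(cells)
        # number of 1s equals cells up to (and including) the last observed one
        obs = np.flatnonzero(~np.isnan(resp.values[0]))
        expected_ones = (obs[-1] + 1) if obs.size else 0
        assert (row == 1.0).sum() == expected_ones


# ---------------------------------------------------------------- covariates

class TestBuildCovariates:
    def test_control_arms_collapse(self):
        table = pd.DataFrame({"gender": ["woman", "woman"],
                              "condition": ["control-A", "control-B"]})
        cov, _ = build_covariates(table, model_id=3)
        assert cov.gender.tolist() == [1, 1]
        assert cov.condition.tolist() == [0, 0]

    def test_model4_design_row(self):
        table = pd.DataFrame({"gender": ["man"], "condition": ["threat"]})
        cov, design = build_covariates(table, model_id=4)
        assert design.iloc[0].tolist() == [0, 1, 0]

    def test_model1_empty_design(self):
        table = pd.DataFrame({"gender": ["woman"], "condition": ["threat"]})
        _, design = build_covariates(table, model_id=1)
        assert design.shape == (1, 0)

    def test_unknown_model_errors(self):
        table = pd.DataFrame({"gender": [1], "condition": [0]})
        with pytest.raises(ValueError, match="model_id"):
            build_covariates(table, model_id=5)

    def test_numeric_dummies_validated(self):
        table = pd.DataFrame({"gender": [2], "condition": [0]})
        with pytest.raises(ValueError, match="dummy"):
            build_covariates(table, model_id=2)


# ---------------------------------------------------------------- descriptives

class TestDescriptives:
    def test_counts(self, toy_response, toy_covariates):
        ind = code_missingness(toy_response)
        desc = summarize_descriptives(toy_response, ind, toy_covariates)
        np.testing.assert_array_equal(desc.attempted_count, [6, 0, 4, 5, 1, 3])
        np.testing.assert_array_equal(desc.correct_count, [4, 0, 2, 5, 1, 1])
        assert (desc.correct_count <= desc.attempted_count).all()

    def test_equal_means_give_zero_d(self):
        out = cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert out["d"] == pytest.approx(0.0)

    def test_unit_separation_gives_minus_one(self):
        base = np.tile([-1.0, 1.0], 500)
        out = cohens_d(1.0 + base, 2.0 + base)
        assert out["d"] == pytest.approx(-1.0, abs=0.01)
        assert out["ci_low"] < out["d"] < out["ci_high"]

    def test_monte_carlo_gap_recovery(self):
        rng = np.random.default_rng(42)
        women = rng.normal(-0.3, 1.0, 10_000)
        men = rng.normal(0.0, 1.0, 10_000)
        out = cohens_d(women, men)
        assert out["d"] == pytest.approx(-0.3, abs=0.05)

    def test_small_group_flagged_not_dropped(self):
        out = cohens_d([1.0], [2.0, 3.0])
        assert np.isnan(out["d"]) and out["flag"] is not None

    def test_both_proportion_conventions_reported(self, toy_response, toy_covariates):
        ind = code_missingness(toy_response)
        desc = summarize_descriptives(toy_response, ind, toy_covariates)
        assert 0.0 <= desc.proportion_correct_aggregate <= 1.0
        assert 0.0 <= desc.proportion_correct_per_person <= 1.0

    def test_per_item_proportions_in_unit_interval(self, toy_response, toy_covariates):
        ind = code_missingness(toy_response)
        desc = summarize_descriptives(toy_response, ind, toy_covariates)
        assert desc.per_item["prop_attempted"].between(0, 1).all()
        assert desc.per_item["prop_correct"].between(0, 1).all()
        assert set(desc.per_item["group"]) == {"all", "women", "men"}


# ---------------------------------------------------------------- alpha

class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([1, 0, 1, 1, 0], dtype=float)
        resp = ResponseMatrix(np.column_stack([col] * 4))
        assert cronbach_alpha(resp)["alpha"] == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        resp = ResponseMatrix((rng.random((4000, 6)) < 0.5).astype(float))
        assert abs(cronbach_alpha(resp)["alpha"]) < 0.1

    def test_hand_computed_three_item_value(self):
        # item variances 0.3 each, total-score variance 1.2
        # -> alpha = 1.5 * (1 - 0.9/1.2) = 0.375
        values = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1], [1, 1, 1], [0, 0, 0]], float)
        out = cronbach_alpha(ResponseMatrix(values), scoring_rule="missing_as_wrong")
        assert out["alpha"] == pytest.approx(0.375)

    def test_zero_total_variance_errors(self):
        resp = ResponseMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(resp)

    def test_scoring_rule_recorded(self):
        resp = ResponseMatrix(np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 1]], float))
        out = cronbach_alpha(resp, scoring_rule="missing_as_wrong")
        assert out["scoring_rule"] == "missing_as_wrong"


def test_design_matrix_columns(toy_covariates):
    assert list(design_matrix(toy_covariates, 1).columns) == []
    assert list(design_matrix(toy_covariates, 2).columns) == ["gender"]
    assert list(design_matrix(toy_covariates, 3).columns) == ["condition"]
    assert list(design_matrix(toy_covariates, 4).columns) == [
        "gender", "condition", "gender_x_condition"]
    d4 = design_matrix(toy_covariates, 4)
    np.testing.assert_array_equal(
        d4["gender_x_condition"], toy_covariates.gender * toy_covariates.condition)
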