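"""Pearson screening, OLS subset fits, and the exhaustive search."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutprop.errors import (
    CollinearityError,
    InsufficientDataError,
    SearchSpaceError,
    UndefinedStatisticError,
)
from mutprop.regression import (
    correlate_all,
    exhaustive_subset_search,
    fit_multiple_regression,
    pearson_r,
    predict,
    search_space_size,
)


def random_frame(n, p, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"c{i:02d}" for i in range(p)]
    )


class TestPearson:
    def test_exact_linearity(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # N=4: S_xy = 29, S_x = S_y = 10, S_xx = S_yy = 30 -> 16/20
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_errors(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 2], [3, 4])

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_invariance_and_sign_flip(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert pearson_r(-a * x, y) == pytest.approx(-r, abs=1e-9)


class TestCorrelateAll:
    def test_exact_column_ranks_first(self):
        frame = random_frame(10, 5, seed=1)
        y = frame["c03"].to_numpy()
        results, skipped = correlate_all(frame, y)
        assert results[0].column_id == "c03"
        assert results[0].r == pytest.approx(1.0)
        assert skipped == []

    def test_constant_column_reported_as_skipped(self):
        frame = random_frame(10, 3, seed=2)
        frame["flat"] = 1.0
        results, skipped = correlate_all(frame, frame["c00"].to_numpy())
        assert skipped == ["flat"]
        assert len(results) == 3

    def test_shuffled_response_below_one(self):
        frame = random_frame(10, 4, seed=3)
        y = np.random.default_rng(9).permutation(frame["c00"].to_numpy())
        results, _ = correlate_all(frame, y)
        assert all(abs(c.r) < 1 for c in results)


class TestFit:
    def test_exact_single_column_fit(self):
        x = np.arange(10.0)
        frame = pd.DataFrame({"x": x})
        res = fit_multiple_regression(frame, 2 + 3 * x)
        assert res.intercept == pytest.approx(2.0)
        assert res.slopes[0] == pytest.approx(3.0)
        assert res.R == pytest.approx(1.0)

    def test_single_column_R_equals_abs_r(self):
        frame = random_frame(15, 1, seed=4)
        y = np.random.default_rng(5).normal(size=15)
        res = fit_multiple_regression(frame, y)
        assert res.R == pytest.approx(abs(pearson_r(frame["c00"], y)), abs=1e-10)

    def test_saturated_fit_refused_then_overridable(self):
        frame = random_frame(6, 5, seed=6)
        y = np.random.default_rng(7).normal(size=6)
        with pytest.raises(InsufficientDataError):
            fit_multiple_regression(frame, y)
        res = fit_multiple_regression(frame, y, allow_saturated=True)
        assert res.R > 0.9  # saturation: near-interpolation is the documented hazard

    def test_duplicate_column_collinearity_named(self):
        frame = random_frame(12, 2, seed=8)
        frame["dup"] = frame["c01"]
        with pytest.raises(CollinearityError) as err:
            fit_multiple_regression(frame, np.arange(12.0))
        assert err.value.columns  # names at least one dependent column

    def test_predict_reproduces_fitted_and_handles_new_rows(self):
        frame = random_frame(12, 3, seed=9)
        y = np.random.default_rng(10).normal(size=12)
        res = fit_multiple_regression(frame, y)
        np.testing.assert_allclose(predict(res, frame), res.fitted, atol=1e-10)
        zero = pd.DataFrame(np.zeros((1, 3)), columns=frame.columns)
        assert predict(res, zero)[0] == pytest.approx(res.intercept)
        row = pd.DataFrame([[1.0, 2.0, -1.0]], columns=frame.columns)
        manual = res.intercept + res.slopes @ np.array([1.0, 2.0, -1.0])
        assert predict(res, row)[0] == pytest.approx(manual, abs=1e-12)
        with pytest.raises(KeyError):
            predict(res, frame[["c00"]])


class TestExhaustiveSearch:
    def test_noiseless_pair_identified_exactly(self):
        frame = random_frame(20, 8, seed=11)
        y = 1.0 + 2.0 * frame["c03"] - 1.5 * frame["c07"]
        report = exhaustive_subset_search(frame, y.to_numpy(), sizes=[2])
        assert report.best.column_ids == ("c03", "c07")
        assert report.best.R == pytest.approx(1.0, abs=1e-10)

    def test_model_count_is_sum_of_binomials(self):
        frame = random_frame(20, 7, seed=12)
        y = np.random.default_rng(13).normal(size=20)
        report = exhaustive_subset_search(frame, y, sizes=[1, 2, 3])
        assert report.n_models == sum(math.comb(7, s) for s in (1, 2, 3))
        assert report.n_models == search_space_size(7, (1, 2, 3))

    def test_size1_matches_top_single_correlation(self):
        frame = random_frame(25, 10, seed=14)
        y = np.random.default_rng(15).normal(size=25)
        report = exhaustive_subset_search(frame, y, sizes=[1])
        results, _ = correlate_all(frame, y)
        assert report.best.R == pytest.approx(abs(results[0].r), abs=1e-10)
        assert report.best.column_ids == (results[0].column_id,)

    def test_ceiling_refusal_reports_size(self):
        frame = random_frame(30, 20, seed=16)
        y = np.random.default_rng(17).normal(size=30)
        with pytest.raises(SearchSpaceError) as err:
            exhaustive_subset_search(frame, y, sizes=[1, 2, 3], max_models=100)
        assert err.value.n_models == search_space_size(20, (1, 2, 3))

    def test_saturation_guard_applies_to_sizes(self):
        frame = random_frame(6, 8, seed=18)
        y = np.random.default_rng(19).normal(size=6)
        with pytest.raises(InsufficientDataError):
            exhaustive_subset_search(frame, y, sizes=[5])

    def test_report_round_trips_to_tsv_and_json(self, tmp_path):
        frame = random_frame(20, 6, seed=20)
        y = np.random.default_rng(21).normal(size=20)
        report = exhaustive_subset_search(frame, y, sizes=[1, 2], top_m=5)
        report.write_tsv(tmp_path / "r.tsv")
        report.write_json(tmp_path / "r.json")
        back = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert list(back["R"]) == pytest.approx([r.R for r in report.results])

    def test_constant_column_excluded_not_fitted(self):
        frame = random_frame(20, 4, seed=22)
        frame["flat"] = 2.5
        y = np.random.default_rng(23).normal(size=20)
        report = exhaustive_subset_search(frame, y, sizes=[1, 2])
        assert report.skipped_columns == ["flat"]
        assert report.n_columns == 4

    def test_matches_independent_brute_force(self):
        """Same best subset and R as a reverse-order brute-force enumerator."""
        frame = random_frame(20, 10, seed=24)
        y = np.random.default_rng(25).normal(size=20)
        report = exhaustive_subset_search(frame, y, sizes=[1, 2, 3])

        best_R, best_cols = -1.0, None
        cols = list(frame.columns)
        for s in (3, 2, 1):
            for combo in reversed(list(itertools.combinations(cols, s))):
                X = np.column_stack([np.ones(20), frame[list(combo)].to_numpy()])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                R = abs(np.corrcoef(X @ beta, y)[0, 1])
                if R > best_R:
                    best_R, best_cols = R, combo
        assert report.best.column_ids == best_cols
        assert report.best.R == pytest.approx(best_R, abs=1e-10)
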