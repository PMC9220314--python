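"""Averaging, single-threshold and multiple-threshold SMF quantifications."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_function_matrix
from soilmultifun import (
    FunctionMatrix,
    average_multifunctionality,
    function_maxima,
    multiple_threshold_analysis,
    shift_nonneg,
    single_threshold_counts,
    threshold_regression,
    zscore_standardize,
)
from soilmultifun.datamodel import ValidationError
from soilmultifun.multifunctionality import default_grid


def brute_force_counts(values, maxima, t):
    """Independent oracle: explicit double loop over plots × functions."""
    out = []
    for i in range(values.shape[0]):
        c = 0
        for j in range(values.shape[1]):
            if values[i, j] >= t * maxima[j]:
                c += 1
        out.append(c)
    return out


class TestZScore:
    def test_simple_column(self):
        fm = FunctionMatrix(pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc")))
        sm = zscore_standardize(fm)
        np.testing.assert_allclose(sm.data["f"], [-1.0, 0.0, 1.0])

    def test_constant_column_errors_unless_dropped(self):
        fm = FunctionMatrix(
            pd.DataFrame({"f": [5.0, 5.0, 5.0], "g": [1.0, 2.0, 3.0]}, index=list("abc"))
        )
        with pytest.raises(ValidationError, match="f"):
            zscore_standardize(fm)
        sm = zscore_standardize(fm, drop_constant=True)
        assert list(sm.data.columns) == ["g"]

    def test_normalization_identity(self, rng):
        fm = random_function_matrix(rng)
        sm = zscore_standardize(fm)
        np.testing.assert_allclose(sm.data.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(sm.data.std(ddof=1), 1.0, atol=1e-10)

    def test_inverse_round_trip(self, rng):
        fm = random_function_matrix(rng, n_plots=8, n_funs=4)
        back = zscore_standardize(fm).inverse()
        pd.testing.assert_frame_equal(back.data, fm.data)


class TestAveraging:
    def test_forced_two_by_two(self):
        fm = FunctionMatrix(
            pd.DataFrame({"f": [1.0, 3.0], "g": [10.0, 30.0]}, index=["a", "b"])
        )
        idx = average_multifunctionality(zscore_standardize(fm))
        # Z rows are (-1/sqrt2 scaled)... with n=2 sample sd: Z = (-0.707, +0.707)
        assert idx["a"] == pytest.approx(-idx["b"])
        assert idx["b"] > 0

    def test_index_sums_to_zero(self, rng):
        fm = random_function_matrix(rng)
        idx = average_multifunctionality(zscore_standardize(fm))
        assert abs(idx.sum()) < 1e-10

    @pytest.mark.parametrize("scale,offset", [(7.0, 3.0), (0.001, -50.0)])
    def test_affine_invariance_of_index(self, rng, scale, offset):
        fm = random_function_matrix(rng)
        idx1 = average_multifunctionality(zscore_standardize(fm))
        data2 = fm.data.copy()
        data2.iloc[:, 0] = data2.iloc[:, 0] * scale + offset
        idx2 = average_multifunctionality(zscore_standardize(FunctionMatrix(data2)))
        np.testing.assert_allclose(idx1, idx2, atol=1e-10)


class TestFunctionMaxima:
    def test_top_fraction_one_is_column_mean(self):
        fm = FunctionMatrix(
            pd.DataFrame({"f": np.arange(1.0, 11.0)}, index=[f"p{i}" for i in range(10)])
        )
        assert function_maxima(fm, top_fraction=1.0)["f"] == pytest.approx(5.5)

    def test_default_top_five_percent_small_n(self):
        # n=10: ceil(0.05*10)=1 value -> the observed maximum
        fm = FunctionMatrix(
            pd.DataFrame({"f": np.arange(1.0, 11.0)}, index=[f"p{i}" for i in range(10)])
        )
        assert function_maxima(fm, top_fraction=0.05)["f"] == pytest.approx(10.0)

    def test_negative_function_errors_and_shift_remedy(self):
        fm = FunctionMatrix(
            pd.DataFrame({"Nm": [-3.0, -2.0, -1.0]}, index=list("abc"))
        )
        with pytest.raises(ValidationError, match="shift_nonneg"):
            function_maxima(fm)
        shifted = shift_nonneg(fm)
        assert shifted.data["Nm"].min() == 0.0
        assert function_maxima(shifted)["Nm"] > 0


class TestSingleThresholdCounts:
    def test_all_at_maximum(self, rng):
        vals = np.tile(np.linspace(1, 2, 10), (5, 1))
        fm = FunctionMatrix(
            pd.DataFrame(vals, index=[f"p{i}" for i in range(5)], columns=[f"F{j}" for j in range(10)])
        )
        maxima = fm.data.max()
        counts = single_threshold_counts(fm, maxima, 0.9)
        assert (counts == 10).all()

    def test_hand_computed(self):
        fm = FunctionMatrix(
            pd.DataFrame([[4.0, 1.0, 9.0]], index=["p"], columns=list("abc"))
        )
        maxima = pd.Series([10.0, 10.0, 10.0], index=list("abc"))
        assert single_threshold_counts(fm, maxima, 0.5)["p"] == 1

    def test_monotonicity_in_threshold(self, rng):
        fm = random_function_matrix(rng)
        maxima = function_maxima(fm)
        prev = None
        for t in default_grid():
            c = single_threshold_counts(fm, maxima, float(t))
            if prev is not None:
                assert (c <= prev).all()
            prev = c

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            fm = random_function_matrix(rng)
            maxima = function_maxima(fm)
            for t in (0.1, 0.5, 0.9):
                got = single_threshold_counts(fm, maxima, t)
                want = brute_force_counts(fm.values, maxima.to_numpy(), t)
                assert list(got) == want


class TestThresholdRegression:
    def test_exact_line(self):
        rich = pd.Series(np.arange(10.0))
        counts = 0.1 * rich + 2
        r = threshold_regression(counts, rich)
        assert r.slope == pytest.approx(0.1)
        assert r.r_squared == pytest.approx(1.0)
        assert r.pvalue < 1e-10

    def test_flat_response(self):
        rich = pd.Series(np.arange(10.0))
        r = threshold_regression(pd.Series([3.0] * 10), rich)
        assert r.slope == 0.0 and r.pvalue == 1.0

    def test_closed_form_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = threshold_regression(pd.Series(y), pd.Series(x))
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert r.slope == pytest.approx(slope, abs=1e-12)

    def test_constant_richness_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate predictor"):
            threshold_regression(pd.Series([1.0, 2.0, 3.0]), pd.Series([5.0, 5.0, 5.0]))


def _designed_step_matrix(rng, slope=0.2, n_plots=30, n_funs=10):
    """Plots hold k_i ~ slope*richness + noise functions at a mid level
    (counted for thresholds up to 45%) and the rest far below; the curve is
    flat beyond 45%."""
    richness = pd.Series(
        np.arange(1.0, n_plots + 1.0), index=[f"p{i}" for i in range(n_plots)]
    )
    k = np.clip(np.round(slope * richness + rng.normal(0, 0.7, n_plots)), 0, n_funs)
    vals = np.full((n_plots, n_funs), 0.02)
    for i, ki in enumerate(k.astype(int)):
        vals[i, :ki] = 0.45
    fm = FunctionMatrix(
        pd.DataFrame(vals, index=richness.index, columns=[f"F{j}" for j in range(n_funs)])
    )
    maxima = pd.Series(1.0, index=fm.data.columns)
    return fm, maxima, richness


class TestMultipleThreshold:
    def test_recovers_designed_effect_band(self, rng):
        fm, maxima, richness = _designed_step_matrix(rng)
        curve = multiple_threshold_analysis(fm, maxima, richness)
        assert curve.t_min is not None
        assert 5 <= curve.t_min <= 45
        assert curve.t_min <= curve.t_mde <= 45
        # R_mde within 3 SE of the designed 0.2 functions per unit richness
        at_mde = curve.table.loc[curve.table["threshold"] == curve.t_mde / 100].iloc[0]
        assert abs(curve.r_mde - 0.2) < 3 * at_mde["stderr"]
        # flat beyond the designed band: slope 0, p 1
        beyond = curve.table[curve.table["threshold"] > 0.45]
        assert (beyond["slope"] == 0).all() and (beyond["pvalue"] == 1.0).all()

    def test_single_point_grid(self, rng):
        fm = random_function_matrix(rng)
        maxima = function_maxima(fm)
        rich = pd.Series(rng.normal(100, 10, 30), index=fm.data.index)
        curve = multiple_threshold_analysis(fm, maxima, rich, grid=np.array([0.5]))
        assert len(curve.table) == 1
        assert curve.t_mde == 50.0

    def test_tmde_tie_break_smallest(self):
        # identical plots -> counts constant at every threshold -> all slopes
        # tie at 0 -> T_mde must be the first (smallest) grid point
        fm = FunctionMatrix(
            pd.DataFrame(
                np.tile([1.0, 3.0, 5.0, 7.0], (3, 1)),
                index=list("abc"),
                columns=list("wxyz"),
            )
        )
        maxima = pd.Series(10.0, index=list("wxyz"))
        rich = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        curve = multiple_threshold_analysis(fm, maxima, rich, grid=np.array([0.2, 0.4, 0.6]))
        assert (curve.table["slope"] == 0).all()
        assert curve.t_mde == 20.0
        assert curve.t_min is None

    def test_r_mde_consistency(self, default_dataset):
        ds = default_dataset
        maxima = function_maxima(ds.function_matrix)
        curve = multiple_threshold_analysis(
            ds.function_matrix, maxima, ds.ground_truth.latent_fungal_richness
        )
        assert curve.r_mde == pytest.approx(curve.table["slope"].max())
        attained = curve.table.loc[curve.table["slope"].idxmax(), "threshold"] * 100
        assert curve.t_mde == pytest.approx(attained)
        if curve.t_min is not None:
            assert curve.t_min in set(np.round(curve.table["threshold"] * 100))
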