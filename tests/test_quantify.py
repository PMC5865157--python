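"""Intercomparison regression, precision, detection limits, composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from breathvoc import (CalibrationSeries, Platform, class_composition,
                       fit_paired_response, lod_from_calibration, relative_sd)
from breathvoc.errors import (DegenerateFitError, InputError,
                              UndefinedStatisticError)


class TestPairedRegression:
    def test_exact_line_recovered(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        slope, intercept, r2 = fit_paired_response(x, [2 * v for v in x])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_x_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_paired_response([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(InputError):
            fit_paired_response([1.0, 2.0], [1.0, 2.0])

    def test_noisy_recovery_at_instrument_magnitude(self):
        # slope of order 3e15 counts/mol, as between a GC detector and
        # molar loading; 5% gaussian response noise
        rng = np.random.default_rng(42)
        loadings = np.array([1, 2, 4, 6, 8, 10, 15]) * 1e-10
        truth = 3e15
        y = truth * loadings * (1 + rng.normal(0, 0.05, loadings.size))
        slope, _, r2 = fit_paired_response(loadings, y)
        assert slope == pytest.approx(truth, rel=0.10)
        assert r2 > 0.9

    @given(c=st.floats(min_value=0.1, max_value=50))
    def test_scale_equivariance(self, c):
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        y = [2.0, 3.9, 6.1, 10.2, 15.8]
        s0, i0, r0 = fit_paired_response(x, y)
        s1, i1, r1 = fit_paired_response(x, [c * v for v in y])
        assert s1 == pytest.approx(c * s0)
        assert i1 == pytest.approx(c * i0)
        assert r1 == pytest.approx(r0)


class TestRelativeSd:
    def test_identical_replicates(self):
        assert relative_sd([10, 10, 10]) == 0.0

    def test_hand_computed_triplicate(self):
        assert relative_sd([9, 10, 11]) == pytest.approx(10.0)

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            relative_sd([-1.0, 1.0])

    def test_monte_carlo_recovers_true_cv(self):
        rng = np.random.default_rng(7)
        rsds = [relative_sd(100 * (1 + rng.normal(0, 0.09, 3)))
                for _ in range(400)]
        # E[RSD] for n=3 gaussian replicates is slightly below the true CV
        assert np.mean(rsds) == pytest.approx(9.0, rel=0.15)


def _series(slope=2.0, loading_to_ppbv=1.0):
    loadings = [1.0, 2.0, 4.0, 8.0]
    return CalibrationSeries(
        compound="butanal", platform=Platform.SIFT_H3O,
        points=[(l, slope * l) for l in loadings],
        loading_to_ppbv=loading_to_ppbv)


class TestLod:
    def test_zero_blank_zero_lod(self):
        assert lod_from_calibration(_series(), 0.0) == 0.0

    def test_homogeneous_in_blank_sd(self):
        one = lod_from_calibration(_series(), 1.0)
        assert lod_from_calibration(_series(), 2.0) == pytest.approx(2 * one)

    def test_hand_computed_value(self):
        # slope 2 per loading unit, blank sd 1.2, 0.5 ppbv per unit:
        # 3.3 * 1.2 / 2 * 0.5 = 0.99 ppbv
        assert lod_from_calibration(_series(2.0, 0.5), 1.2) == \
            pytest.approx(0.99)

    def test_decreasing_in_slope(self):
        assert lod_from_calibration(_series(4.0), 1.0) < \
            lod_from_calibration(_series(2.0), 1.0)

    def test_negative_slope_undefined(self):
        bad = CalibrationSeries("x", Platform.EI,
                                [(1.0, 5.0), (2.0, 3.0), (4.0, 1.0)])
        with pytest.raises(UndefinedStatisticError):
            lod_from_calibration(bad, 1.0)


class TestComposition:
    def test_already_normalised_profile(self):
        areas = pd.DataFrame({
            "sample": ["s1"] * 5,
            "chem_class": ["ketone", "aldehyde", "acid", "phenol", "alcohol"],
            "area": [77.0, 10.0, 9.0, 3.0, 1.0],
        })
        profile = class_composition(areas)
        row = profile.per_sample.loc["s1"]
        assert row["ketone"] == pytest.approx(77.0)
        assert row["alcohol"] == pytest.approx(1.0)
        assert row.sum() == pytest.approx(100.0)

    def test_single_class_is_100_percent(self):
        areas = pd.DataFrame({"sample": ["s1"], "chem_class": ["ketone"],
                              "area": [123.0]})
        profile = class_composition(areas)
        assert profile.per_sample.loc["s1", "ketone"] == pytest.approx(100.0)

    def test_rows_always_sum_to_100(self):
        rng = np.random.default_rng(3)
        areas = pd.DataFrame({
            "sample": np.repeat([f"s{i}" for i in range(6)], 4),
            "chem_class": list("abcd") * 6,
            "area": rng.uniform(0.1, 50, 24),
        })
        sums = class_composition(areas).per_sample.sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_all_zero_areas_undefined(self):
        areas = pd.DataFrame({"sample": ["s1", "s1"],
                              "chem_class": ["ketone", "acid"],
                              "area": [0.0, 0.0]})
        with pytest.raises(UndefinedStatisticError):
            class_composition(areas)

    def test_cohort_median_reported(self):
        areas = pd.DataFrame({
            "sample": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "chem_class": ["ketone", "acid"] * 3,
            "area": [70, 30, 80, 20, 75, 25],
        })
        profile = class_composition(areas)
        assert profile.median("ketone") == pytest.approx(75.0)
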