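import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn
from scipy import stats as sps

from amineblot.calibration import (
    CalibrationModel,
    CalibrationSpot,
    FenceParams,
    calibrate_batch,
    ci_mean_response,
    estimate_resolution,
    fence_outliers,
    fit_calibration,
    flag_outlier_papers,
    intensity_to_conc,
    quartiles,
    spots_from_table,
)
from amineblot.errors import DataError, DegenerateModelError
from amineblot.synthetic_fixtures import (
    DEFAULT_INTERCEPT,
    DEFAULT_SLOPE,
    DEFAULT_STANDARDS,
    OutlierSpec,
    make_calibration_batch,
)


def brute_fence_flags(values, k=0.5):
    """Independent oracle: sorted-list linear-interpolation quartiles plus
    explicit fence arithmetic, no numpy."""
    s = sorted(values)
    n = len(s)

    def quantile(p):
        h = (n - 1) * p
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return [v < q1 - k * iqr or v > q3 + k * iqr for v in values]


class TestQuartiles:
    def test_worked_example(self):
        q1, q3, iqr = quartiles([1, 2, 3, 4])
        assert (q1, q3, iqr) == (1.75, 3.25, 1.5)

    def test_constant_list(self):
        q1, q3, iqr = quartiles([5, 5, 5, 5])
        assert q1 == q3 == 5 and iqr == 0

    def test_too_few(self):
        with pytest.raises(DataError):
            quartiles([1])


class TestFenceOutliers:
    def test_single_extreme(self):
        flags = fence_outliers([10, 10, 10, 10, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_list_no_flags(self):
        assert not fence_outliers([7, 7, 7, 7]).any()

    def test_symmetric_no_extremes(self):
        values = [10, 12, 14, 16, 18, 20]
        assert fence_outliers(values).tolist() == brute_fence_flags(values)

    @given(
        stn.lists(stn.integers(min_value=0, max_value=20), min_size=2, max_size=10),
        stn.floats(min_value=0.1, max_value=3.0),
    )
    @settings(max_examples=200)
    def test_agrees_with_brute_force(self, values, k):
        fence = FenceParams(k=k)
        assert fence_outliers(values, fence).tolist() == brute_fence_flags(values, k)


def _batch_spots(df):
    return spots_from_table(df)


class TestFlagOutlierPapers:
    def test_shifted_paper_removed(self):
        df, _ = make_calibration_batch(
            n_papers=6,
            noise_sd=0.0,
            outliers=[OutlierSpec("paper02", 3.41, shift=60.0, n_spots=3)],
            seed=7,
        )
        spots = _batch_spots(df)
        report = flag_outlier_papers(spots)
        assert report.removed == ("paper02",)
        assert 3.41 in report.reasons["paper02"]
        # manual oracle on the pooled 3.41 mM intensities
        vals = [s.mean_intensity for s in spots if s.concentration == 3.41]
        ids = [s.paper_id for s in spots if s.concentration == 3.41]
        flags = brute_fence_flags(vals)
        n_flagged = sum(f for f, p in zip(flags, ids) if p == "paper02")
        assert n_flagged >= 2

    def test_all_identical_retained(self):
        df, _ = make_calibration_batch(n_papers=4, noise_sd=0.0)
        report = flag_outlier_papers(_batch_spots(df))
        assert report.removed == ()
        assert len(report.retained) == 4

    def test_single_flag_per_concentration_retained(self):
        # paper03 gets exactly one shifted spot at each concentration
        spots = []
        for p in range(5):
            pid = f"paper{p:02d}"
            for c in DEFAULT_STANDARDS:
                base = DEFAULT_SLOPE * c + DEFAULT_INTERCEPT
                for rep in range(3):
                    v = base + (30.0 if (pid == "paper03" and rep == 0) else rep * 0.1)
                    spots.append(CalibrationSpot(pid, c, v))
        report = flag_outlier_papers(spots)
        assert "paper03" in report.retained

    def test_missing_concentration_errors(self):
        spots = [
            CalibrationSpot("a", 1.71, 200.0),
            CalibrationSpot("a", 3.41, 170.0),
            CalibrationSpot("b", 1.71, 201.0),
        ]
        with pytest.raises(DataError, match="b.*3.41"):
            flag_outlier_papers(spots)

    def test_order_invariant(self, rng):
        df, _ = make_calibration_batch(
            n_papers=8, noise_sd=3.0, outliers=[OutlierSpec("paper05", 1.71)], seed=3
        )
        spots = _batch_spots(df)
        shuffled = [spots[i] for i in rng.permutation(len(spots))]
        assert flag_outlier_papers(spots).removed == flag_outlier_papers(shuffled).removed


class TestFitCalibration:
    def test_recovers_published_line_exactly(self):
        df, _ = make_calibration_batch(n_papers=1, noise_sd=0.0)
        model = fit_calibration(_batch_spots(df))
        assert model.slope == pytest.approx(DEFAULT_SLOPE, abs=1e-9)
        assert model.intercept == pytest.approx(DEFAULT_INTERCEPT, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_unit_slope(self):
        spots = [CalibrationSpot("p", float(x), float(x)) for x in (1, 2, 3)]
        model = fit_calibration(spots)
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_library_oracle_on_noisy_data(self):
        df, _ = make_calibration_batch(n_papers=4, noise_sd=5.0, seed=11)
        spots = _batch_spots(df)
        x = np.array([s.concentration for s in spots])
        y = np.array([s.mean_intensity for s in spots])
        oracle = sps.linregress(x, y)
        model = fit_calibration(spots)
        assert model.slope == pytest.approx(oracle.slope, abs=1e-9)
        assert model.intercept == pytest.approx(oracle.intercept, abs=1e-9)
        assert model.r_squared == pytest.approx(oracle.rvalue**2, abs=1e-9)
        assert model.p_value == pytest.approx(oracle.pvalue, abs=1e-9)

    def test_degenerate_design(self):
        spots = [CalibrationSpot("p", 2.0, v) for v in (10.0, 11.0, 12.0)]
        with pytest.raises(DegenerateModelError):
            fit_calibration(spots)

    def test_too_few_spots(self):
        with pytest.raises(DataError):
            fit_calibration([CalibrationSpot("p", 1.0, 1.0), CalibrationSpot("p", 2.0, 2.0)])

    def test_json_round_trip(self, tmp_path):
        df, _ = make_calibration_batch(n_papers=2, noise_sd=2.0, seed=5)
        model = fit_calibration(_batch_spots(df))
        path = tmp_path / "model.json"
        model.to_json(path)
        assert CalibrationModel.from_json(path) == model


class TestCiMeanResponse:
    def test_noise_free_zero_width(self, noise_free_model):
        lo, hi = ci_mean_response(noise_free_model, 3.41)
        assert lo == hi

    def test_width_minimal_at_x_mean(self):
        df, _ = make_calibration_batch(n_papers=3, noise_sd=5.0, seed=2)
        model = fit_calibration(_batch_spots(df))
        w_center = np.diff(ci_mean_response(model, model.x_mean))[0]
        w_edge = np.diff(ci_mean_response(model, model.x_mean + 3.0))[0]
        assert w_center < w_edge

    def test_matches_textbook_formula(self):
        df, _ = make_calibration_batch(n_papers=3, noise_sd=5.0, seed=9)
        model = fit_calibration(_batch_spots(df))
        x = 2.5
        t = sps.t.ppf(0.975, model.n - 2)
        half = t * model.residual_se * np.sqrt(
            1 / model.n + (x - model.x_mean) ** 2 / model.sxx
        )
        yhat = model.slope * x + model.intercept
        lo, hi = ci_mean_response(model, x)
        assert lo == pytest.approx(yhat - half, abs=1e-9)
        assert hi == pytest.approx(yhat + half, abs=1e-9)

    def test_matches_statsmodels_oracle(self):
        import pandas as pd
        import statsmodels.formula.api as smf

        df, _ = make_calibration_batch(n_papers=3, noise_sd=4.0, seed=13)
        spots = _batch_spots(df)
        data = pd.DataFrame(
            {"x": [s.concentration for s in spots], "y": [s.mean_intensity for s in spots]}
        )
        fit = smf.ols("y ~ x", data=data).fit()
        pred = fit.get_prediction(pd.DataFrame({"x": [2.2]})).conf_int(alpha=0.05)
        model = fit_calibration(spots)
        lo, hi = ci_mean_response(model, 2.2)
        assert lo == pytest.approx(pred[0, 0], abs=1e-8)
        assert hi == pytest.approx(pred[0, 1], abs=1e-8)

    def test_prediction_interval_wider(self):
        df, _ = make_calibration_batch(n_papers=3, noise_sd=5.0, seed=4)
        model = fit_calibration(_batch_spots(df))
        ci = ci_mean_response(model, 3.0)
        pi = ci_mean_response(model, 3.0, prediction=True)
        assert pi[0] < ci[0] < ci[1] < pi[1]


class TestIntensityToConc:
    def test_intercept_maps_to_zero(self, noise_free_model):
        assert intensity_to_conc(noise_free_model, DEFAULT_INTERCEPT) == 0.0

    def test_round_trip_identity(self, noise_free_model):
        for c in np.linspace(0.0, 4.71, 25):
            y = noise_free_model.predict(c)
            assert intensity_to_conc(noise_free_model, float(y)) == pytest.approx(c, abs=1e-9)

    def test_brighter_than_intercept_clamps_to_zero(self, noise_free_model):
        assert intensity_to_conc(noise_free_model, 250.0) == 0.0

    def test_darker_than_top_standard_clamps_to_max(self, noise_free_model):
        assert intensity_to_conc(noise_free_model, 0.0) == 4.71

    def test_zero_slope_errors(self, noise_free_model):
        from dataclasses import replace

        with pytest.raises(DegenerateModelError):
            intensity_to_conc(replace(noise_free_model, slope=0.0), 100.0)


class TestEstimateResolution:
    def test_noise_free_all_zero(self, noise_free_model):
        ranges, mean = estimate_resolution(noise_free_model, DEFAULT_STANDARDS)
        assert ranges == [0.0, 0.0, 0.0] and mean == 0.0

    def test_intensity_range_divided_by_slope(self):
        df, _ = make_calibration_batch(n_papers=3, noise_sd=5.0, seed=21)
        model = fit_calibration(_batch_spots(df))
        ranges, mean = estimate_resolution(model, DEFAULT_STANDARDS)
        for x, r in zip(DEFAULT_STANDARDS, ranges):
            lo, hi = ci_mean_response(model, x)
            assert r == pytest.approx((hi - lo) / abs(model.slope), abs=1e-12)
        assert mean == pytest.approx(np.mean(ranges), abs=1e-12)

    def test_hand_example(self):
        # a CI intensity range of 19 units with |slope| 20.98 is 0.906 mM
        assert 19 / 20.98 == pytest.approx(0.9056, abs=5e-4)

    def test_empty_standards(self, noise_free_model):
        with pytest.raises(DataError):
            estimate_resolution(noise_free_model, [])


class TestCalibrateBatch:
    def test_outliers_excluded_but_reported(self):
        df, _ = make_calibration_batch(
            n_papers=6, noise_sd=1.0, outliers=[OutlierSpec("paper01", 4.71, n_spots=3)], seed=8
        )
        model, report = calibrate_batch(_batch_spots(df))
        assert "paper01" in report.removed
        assert "paper01" in model.removed_papers
        assert "paper01" not in model.retained_papers
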