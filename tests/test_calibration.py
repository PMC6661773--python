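"""Calibration fitting, back-calculation and curve acceptance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plasmaquant.calibration import (
    CalibrationModel,
    CalibrationStandard,
    assess_curve,
    back_calculate,
    fit_calibration,
)
from tests.conftest import MET_LEVELS, MET_LINE


def _grid_search_wls(x, y, w, zooms=60, pts=41, shrink=0.6):
    """Independent oracle: zooming grid search of sum w*(y - a - b*x)^2.

    The windows shrink gently (x0.6 per zoom) because the SSE valley is
    strongly correlated in (a, b); an aggressive zoom stalls off-axis.
    """
    # crude independent start: two-point slope through the range endpoints;
    # windows on the data scale so the optimum is inside the first grid
    b = (y[-1] - y[0]) / (x[-1] - x[0])
    a = float(np.mean(y) - b * np.mean(x))
    wb = 2.0 * abs(b) + 1e-6
    wa = float(np.max(np.abs(y))) + 1e-3
    for _ in range(zooms):
        bs = np.linspace(b - wb, b + wb, pts)
        as_ = np.linspace(a - wa, a + wa, pts)
        sse = ((y[None, None, :] - as_[:, None, None]
                - bs[None, :, None] * x[None, None, :]) ** 2 * w).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        a, b = float(as_[i]), float(bs[j])
        wa *= shrink
        wb *= shrink
    return a, b


class TestFit:
    def test_noise_free_standards_recover_printed_line(self, met_standards):
        curve = fit_calibration(met_standards, weighting="none", analyte="MET")
        slope, intercept = MET_LINE
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)
        assert curve.r == pytest.approx(1.0, abs=1e-10)
        assert (curve.range_low, curve.range_high) == (50, 5000)

    def test_identity_line(self):
        standards = [CalibrationStandard(x, float(x)) for x in (1, 2, 5, 10)]
        curve = fit_calibration(standards)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weighting", ["none", "1/x", "1/x2"])
    def test_weighted_fit_matches_grid_search_oracle(self, weighting):
        rng = np.random.default_rng(5)
        x = np.array(MET_LEVELS, dtype=float)
        y = (MET_LINE[0] * x + MET_LINE[1]) * (1 + rng.normal(0, 0.05, x.size))
        standards = [CalibrationStandard(float(xi), float(yi))
                     for xi, yi in zip(x, y)]
        curve = fit_calibration(standards, weighting=weighting)
        w = {"none": np.ones_like(x), "1/x": 1 / x, "1/x2": 1 / x**2}[weighting]
        a, b = _grid_search_wls(x, y, w)
        assert curve.intercept == pytest.approx(a, abs=1e-6)
        assert curve.slope == pytest.approx(b, abs=1e-6)

    def test_r_squared_matches_brute_force_weighted_correlation(self):
        rng = np.random.default_rng(9)
        x = np.array(MET_LEVELS, dtype=float)
        y = 0.002 * x + rng.normal(0, 0.1, x.size)
        standards = [CalibrationStandard(float(xi), float(yi))
                     for xi, yi in zip(x, y)]
        curve = fit_calibration(standards, weighting="1/x")
        w = 1 / x
        xm, ym = np.average(x, weights=w), np.average(y, weights=w)
        r_oracle = (np.sum(w * (x - xm) * (y - ym))
                    / np.sqrt(np.sum(w * (x - xm) ** 2)
                              * np.sum(w * (y - ym) ** 2)))
        assert curve.r**2 == pytest.approx(r_oracle**2, abs=1e-12)

    def test_blanks_and_zeros_excluded_from_fit(self, met_standards):
        spiked = met_standards + [
            CalibrationStandard(None, 0.0, role="blank"),
            CalibrationStandard(None, 0.5, role="zero"),  # gross zero response
        ]
        curve = fit_calibration(spiked)
        assert curve.slope == pytest.approx(MET_LINE[0], abs=1e-10)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            CalibrationModel([CalibrationStandard(100.0, 1.0)])
        with pytest.raises(ValueError):
            CalibrationModel([CalibrationStandard(100.0, 1.0),
                              CalibrationStandard(100.0, 1.1)])


class TestBackCalculation:
    def test_printed_line_inverts_to_lloq(self, met_standards):
        curve = fit_calibration(met_standards)
        # forward-evaluated ratio at 50 ng/mL: 0.0016*50 - 0.0088 = -0.0008
        ratio = MET_LINE[0] * 50 + MET_LINE[1]
        assert back_calculate(curve, ratio).conc == pytest.approx(50.0, rel=1e-9)

    def test_ratio_equal_intercept_gives_zero(self, met_standards):
        curve = fit_calibration(met_standards)
        res = back_calculate(curve, curve.intercept)
        assert res.conc == pytest.approx(0.0, abs=1e-12)
        assert not res.in_range

    def test_out_of_range_flagged(self, met_standards):
        curve = fit_calibration(met_standards)
        ratio = MET_LINE[0] * 6000 + MET_LINE[1]
        res = back_calculate(curve, ratio)
        assert res.conc == pytest.approx(6000.0, rel=1e-9)
        assert not res.in_range and not res.blq

    def test_negative_back_calc_flagged_blq(self, met_standards):
        curve = fit_calibration(met_standards)
        res = back_calculate(curve, curve.intercept - 0.01)
        assert res.blq

    def test_round_trip_reproduces_nominals(self, met_standards):
        results = CalibrationModel(met_standards).fit()
        for s in met_standards:
            bc = results.back_calculate(s.response_ratio)
            assert bc.conc == pytest.approx(s.nominal, rel=1e-9)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scaling_ratios_scales_line_and_preserves_backcalc(self, c):
        base = [CalibrationStandard(x, MET_LINE[0] * x + MET_LINE[1])
                for x in MET_LEVELS]
        scaled = [CalibrationStandard(s.nominal, c * s.response_ratio)
                  for s in base]
        curve0 = fit_calibration(base)
        curve1 = fit_calibration(scaled)
        assert curve1.slope == pytest.approx(c * curve0.slope, rel=1e-9)
        assert curve1.intercept == pytest.approx(c * curve0.intercept, rel=1e-9)
        for s in base:
            assert back_calculate(curve1, c * s.response_ratio).conc == \
                pytest.approx(s.nominal, rel=1e-8)


class TestCurveAcceptance:
    def test_noise_free_standards_all_pass(self, met_standards):
        results = CalibrationModel(met_standards).fit()
        assessment = results.assess()
        assert assessment.curve_passed
        np.testing.assert_allclose(assessment.table["accuracy_pct"], 100.0,
                                   atol=1e-9)

    def test_single_biased_mid_standard_fails_but_curve_passes(self):
        slope, intercept = MET_LINE
        standards = []
        for x in MET_LEVELS:
            bias = 1.16 if x == 500 else 1.0  # +16% at one mid level
            standards.append(
                CalibrationStandard(x, slope * (bias * x) + intercept)
            )
        curve = fit_calibration(
            [CalibrationStandard(x, slope * x + intercept) for x in MET_LEVELS]
        )
        assessment = assess_curve(curve, standards)
        failed = assessment.table.loc[~assessment.table["passed"]]
        assert list(failed["nominal_ng_ml"]) == [500]
        assert assessment.curve_passed  # 7/8 = 87.5% >= 75%, LLOQ+top pass

    def test_lloq_at_81_percent_accuracy_passes_inclusive_20(self):
        slope, intercept = MET_LINE
        curve = fit_calibration(
            [CalibrationStandard(x, slope * x + intercept) for x in MET_LEVELS]
        )
        standards = [CalibrationStandard(50, slope * (0.81 * 50) + intercept)]
        assessment = assess_curve(curve, standards)
        assert bool(assessment.table["passed"].iloc[0])  # |81-100| <= 20

    def test_failing_lloq_fails_curve(self):
        slope, intercept = MET_LINE
        curve = fit_calibration(
            [CalibrationStandard(x, slope * x + intercept) for x in MET_LEVELS]
        )
        standards = [
            CalibrationStandard(
                x, slope * ((0.7 if x == 50 else 1.0) * x) + intercept
            )
            for x in MET_LEVELS
        ]
        assessment = assess_curve(curve, standards)
        assert not assessment.curve_passed


class TestModelInterface:
    def test_from_dataframe_and_summary(self):
        import pandas as pd

        slope, intercept = MET_LINE
        rows = [
            {"analyte": "MET", "role": "standard", "nominal_ng_ml": x,
             "analyte_area": (slope * x + intercept) * 5e4, "is_area": 5e4}
            for x in MET_LEVELS
        ]
        rows.append({"analyte": "MET", "role": "blank", "nominal_ng_ml": 0.0,
                     "analyte_area": 0.0, "is_area": 0.0})
        fit = CalibrationModel.from_dataframe(pd.DataFrame(rows),
                                              analyte="MET").fit()
        assert fit.curve.slope == pytest.approx(slope, abs=1e-10)
        text = fit.summary()
        assert "MET" in text and "ACCEPTED" in text
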