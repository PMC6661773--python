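"""Validation battery: accuracy, precision, recovery, matrix effect,
dilution integrity, stability and selectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plasmaquant.simulate import AssayErrorModel, simulate_qc_battery
from plasmaquant.validation import (
    MET_QC_LEVELS,
    AcceptanceRules,
    accuracy_percent,
    dilution_integrity,
    matrix_factor,
    mean_recovery,
    qc_battery,
    recovery_percent,
    round_half_away,
    rsd_percent,
    selectivity_check,
    stability_battery,
)
from tests.conftest import (
    RECOVERY_CFZ,
    RECOVERY_MET,
    TABLE2_ACCURACY_CELLS,
    TABLE4_ACCURACY_CELLS,
)


class TestAccuracyPercent:
    @pytest.mark.parametrize(
        "mean_found, nominal, expected",
        TABLE2_ACCURACY_CELLS + TABLE4_ACCURACY_CELLS,
    )
    def test_reported_cells_reproduce(self, mean_found, nominal, expected):
        assert accuracy_percent(mean_found, nominal) == expected

    def test_equal_found_and_nominal_is_100(self):
        assert accuracy_percent(123.456, 123.456) == 100.00

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            accuracy_percent(10.0, 0.0)

    @given(st.floats(min_value=0.01, max_value=1e4),
           st.floats(min_value=0.01, max_value=1e4),
           st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, m, n, c):
        a0 = accuracy_percent(m, n, ndigits=None)
        a1 = accuracy_percent(c * m, c * n, ndigits=None)
        assert a1 == pytest.approx(a0, rel=1e-12)


class TestRSDPercent:
    def test_identical_values_zero(self):
        assert rsd_percent([5.0, 5.0, 5.0]) == 0.00

    def test_hand_computed_triplet(self):
        # {1,2,3}: sample SD 1, mean 2 -> 50.00%
        assert rsd_percent([1, 2, 3]) == 50.00

    def test_brute_force_formula(self):
        vals = [10, 10, 10, 10, 10, 12]
        v = np.asarray(vals, float)
        oracle = 100 * v.std(ddof=1) / v.mean()  # 7.90%
        assert rsd_percent(vals) == round_half_away(oracle)
        assert rsd_percent(vals) == 7.90

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            rsd_percent([1.0])

    @given(st.lists(st.floats(min_value=0.5, max_value=100.0), min_size=2,
                    max_size=20),
           st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance_and_oracle(self, values, c):
        v = np.asarray(values)
        if v.mean() == 0:
            return
        full = rsd_percent(values, ndigits=None)
        oracle = 100 * v.std(ddof=1) / v.mean()
        assert full == pytest.approx(oracle, abs=1e-12 * max(1, abs(oracle)))
        scaled = rsd_percent(list(c * v), ndigits=None)
        assert scaled == pytest.approx(full, rel=1e-9)


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away(92.495) == 92.50
        assert round_half_away(1.005) == 1.01
        assert round_half_away(-1.005) == -1.01


class TestQCBattery:
    def _battery(self, bias, seed):
        err = AssayErrorModel(proportional_cv=0.03, lloq=1.0, seed=seed)
        return simulate_qc_battery(MET_QC_LEVELS, replicates=6, days=3,
                                   bias=bias, error=err)

    def test_interday_pools_all_days(self):
        intra, inter, notes = qc_battery(self._battery(0.05, 1))
        assert {r.n for r in intra} == {6}
        assert {r.n for r in inter} == {18}
        assert notes == []

    def test_bias_recovered_within_monte_carlo_error(self):
        accs = []
        for seed in range(10):
            _, inter, _ = qc_battery(self._battery(0.05, seed))
            accs.extend(r.accuracy_pct for r in inter)
        assert np.mean(accs) == pytest.approx(105.0, abs=2.0)

    def test_reported_interday_lqc_cell(self):
        # mean found 161.15 at nominal 150 -> accuracy 107.43
        rows = [{"level": "LQC", "nominal_ng_ml": 150.0, "day": d,
                 "conc_found_ng_ml": c}
                for d, c in [(1, 161.0), (1, 161.3), (2, 161.15), (2, 161.15),
                             (3, 161.2), (3, 161.1)]]
        _, inter, _ = qc_battery(pd.DataFrame(rows))
        assert inter[0].accuracy_pct == pytest.approx(107.43, abs=0.01)

    def test_boundary_pass_fail_rules(self):
        rules = AcceptanceRules()
        assert not rules.passes("LQC", 84.9, 1.0)  # outside +/-15
        assert rules.passes("LQC", 85.0, 15.0)  # inclusive bounds
        assert rules.passes("LLOQ", 80.0, 20.0)  # relaxed LLOQ band
        assert not rules.passes("LLOQ", 79.9, 1.0)
        assert not rules.passes("HQC", 100.0, 15.1)

    def test_missing_level_reported_not_fatal(self):
        df = self._battery(0.0, 0)
        df = df[df["level"] != "MQC"]
        _, inter, notes = qc_battery(df, levels=MET_QC_LEVELS)
        assert any("MQC" in n for n in notes)
        assert {r.level.name for r in inter} == {"LLOQ", "LQC", "HQC"}


class TestRecovery:
    def test_reported_mean_recoveries(self):
        met_levels, met_mean = RECOVERY_MET
        cfz_levels, cfz_mean = RECOVERY_CFZ
        assert mean_recovery(met_levels) == met_mean  # 98.21
        assert mean_recovery(cfz_levels) == cfz_mean  # 94.32

    def test_identical_lists_100(self):
        rec, rsd = recovery_percent([100, 110, 90], [100, 110, 90])
        assert rec == 100.00

    def test_ratio_of_means(self):
        rec, _ = recovery_percent([98.0, 98.0], [100.0, 100.0])
        assert rec == 98.00

    def test_zero_post_extraction_rejected(self):
        with pytest.raises(ValueError):
            recovery_percent([1.0], [0.0])


class TestMatrixEffect:
    def test_all_lots_equal_neat(self):
        res = matrix_factor({f"lot{i}": 100.0 for i in range(6)}, 100.0)
        assert all(v == 1.0 for v in res.mf_per_lot.values())
        assert res.rsd_pct == 0.00 and res.passed

    def test_one_suppressed_lot_fails(self):
        lots = {"a": 50.0, "b": 100.0, "c": 100.0, "d": 100.0, "e": 100.0,
                "f": 100.0}
        res = matrix_factor(lots, 100.0)
        assert res.rsd_pct > 15 and not res.passed

    def test_five_percent_lot_cv_passes(self):
        rng = np.random.default_rng(7)
        lots = {f"lot{i}": 100 * (1 + rng.normal(0, 0.05)) for i in range(6)}
        res = matrix_factor(lots, 100.0)
        assert res.rsd_pct <= 15 and res.passed

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            matrix_factor({"a": 1.0}, 1.0)
        with pytest.raises(ValueError):
            matrix_factor({"a": 1.0, "b": 1.0}, 0.0)


class TestDilutionIntegrity:
    def test_perfect_measurement_100(self):
        res = dilution_integrity([4000.0] * 6, 2, 8000.0)
        assert res.accuracy_pct == 100.00 and res.passed

    def test_reported_met_accuracy(self):
        # measured 3696 ng/mL after 1:2 dilution of an 8000 ng/mL sample
        res = dilution_integrity([3696.0] * 6, 2, 8000.0)
        assert res.accuracy_pct == 92.40

    def test_biased_noisy_replicates(self):
        rng = np.random.default_rng(3)
        measured = 4000 * 0.93 * (1 + rng.normal(0, 0.05, 6))
        res = dilution_integrity(measured, 2, 8000.0)
        assert res.accuracy_pct == pytest.approx(93.0, abs=6.0)
        assert res.passed

    def test_dilution_factor_below_two_rejected(self):
        with pytest.raises(ValueError):
            dilution_integrity([100.0], 1, 200.0)


class TestStability:
    @staticmethod
    def _frame(condition, level, nominal, values):
        return pd.DataFrame(
            [{"condition": condition, "level": level, "nominal_ng_ml": nominal,
              "conc_found_ng_ml": v} for v in values]
        )

    def test_reported_freeze_thaw_cell(self):
        df = self._frame("freeze_thaw", "LQC", 150.0,
                         [141.0, 141.2, 141.1, 141.1])
        res = stability_battery(df)[0]
        assert res.accuracy_pct == pytest.approx(94.07, abs=0.01)

    def test_reported_long_term_cell(self):
        df = self._frame("long_term", "LQC", 30.0, [29.7, 29.84, 29.77])
        res = stability_battery(df)[0]
        assert res.accuracy_pct == pytest.approx(99.23, abs=0.01)

    def test_fresh_reference_ratio(self):
        df = self._frame("short_term", "HQC", 800.0, [800.0, 800.0])
        res = stability_battery(df, fresh_reference={"HQC": 800.0})[0]
        assert res.accuracy_pct == 100.00
        assert res.vs_fresh_pct == 100.00
        assert res.passed

    def test_unknown_condition_rejected(self):
        df = self._frame("microwave", "LQC", 30.0, [29.0, 29.5])
        with pytest.raises(ValueError):
            stability_battery(df)


class TestSelectivity:
    def test_clean_blanks_pass(self):
        res = selectivity_check({f"lot{i}": 0.0 for i in range(6)},
                                [100.0] * 6)
        assert res.passed
        assert all(v == 0.0 for v in res.interference_pct.values())

    def test_quarter_of_lloq_fails(self):
        res = selectivity_check({"lot1": 25.0}, [100.0] * 6)
        assert res.interference_pct["lot1"] == 25.00
        assert not res.passed

    def test_is_threshold_tighter(self):
        res = selectivity_check({"lot1": 10.0}, [100.0] * 6,
                                is_internal_standard=True)
        assert not res.passed  # 10% > 5% IS threshold

    def test_zero_lloq_rejected(self):
        with pytest.raises(ValueError):
            selectivity_check({"lot1": 1.0}, [0.0])


class TestBatteryCalibrationProperty:
    def test_estimated_accuracy_tracks_known_bias(self):
        # full battery with known bias b and cv v: estimated accuracies lie
        # within b +/- 3v/sqrt(n) of 100+b across seeds
        bias, cv, n = 0.08, 0.05, 18
        half_width = 100 * 3 * cv / np.sqrt(n)
        for seed in range(5):
            err = AssayErrorModel(proportional_cv=cv, lloq=1.0, seed=seed)
            df = simulate_qc_battery(MET_QC_LEVELS, 6, 3, bias, err)
            _, inter, _ = qc_battery(df)
            for r in inter:
                assert abs(r.accuracy_pct - 108.0) <= half_width
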