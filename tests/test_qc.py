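"""Measurement filters, two-step outlier detection, method reconciliation."""

import numpy as np
import pandas as pd
import pytest

from mesolim.qc import (
    FilterThresholds,
    apply_measurement_filters,
    detect_outliers,
    reconcile_methods,
    run_qc,
)
from tests.conftest import type7_quartiles


def _frame(**overrides):
    base = {
        "pft": "C3_annual_herb",
        "gm": 0.2,
        "T_meas": 25.0,
        "PPFD": 1500.0,
        "CO2_meas": 400.0,
        "An": 20.0,
    }
    base.update(overrides)
    return pd.DataFrame([base])


class TestMeasurementFilters:
    @pytest.mark.parametrize(
        "overrides, criterion",
        [
            ({"T_meas": 14.0}, "temperature"),
            ({"T_meas": 36.0}, "temperature"),
            ({"T_meas": np.nan}, "temperature"),   # "or not reported"
            ({"PPFD": 299.0}, "irradiance"),
            ({"CO2_meas": 299.0}, "co2"),
            ({"CO2_meas": 501.0}, "co2"),
            ({"An": 30.0, "gm": 0.05}, "drawdown"),   # drawdown 600 > 300
            ({"An": 1.0, "gm": 0.2}, "drawdown"),     # drawdown 5 < 10
        ],
    )
    def test_each_criterion_excludes(self, overrides, criterion):
        retained, report = apply_measurement_filters(_frame(**overrides))
        assert len(retained) == 0
        assert report.n_excluded_by[criterion] == 1
        assert report.excluded_rows[0] == [criterion]

    def test_clean_row_retained(self):
        retained, report = apply_measurement_filters(_frame())
        assert len(retained) == 1
        assert report.n_retained == 1 and not report.excluded_rows

    def test_boundary_values_retained(self):
        for overrides in ({"T_meas": 15.0}, {"T_meas": 35.0}, {"PPFD": 300.0},
                          {"CO2_meas": 300.0}, {"CO2_meas": 500.0}):
            retained, _ = apply_measurement_filters(_frame(**overrides))
            assert len(retained) == 1, overrides

    def test_missing_ppfd_and_co2_retained_with_note(self):
        retained, report = apply_measurement_filters(
            _frame(PPFD=np.nan, CO2_meas=np.nan)
        )
        assert len(retained) == 1
        assert any("PPFD" in n for n in report.notes)
        assert any("CO2" in n for n in report.notes)

    def test_multiple_reasons_counted_once(self):
        retained, report = apply_measurement_filters(_frame(T_meas=10.0, PPFD=100.0))
        assert report.n_retained == 0
        assert sorted(report.excluded_rows[0]) == ["irradiance", "temperature"]
        assert report.n_input == report.n_retained + len(report.excluded_rows)

    def test_thresholds_are_overridable(self):
        th = FilterThresholds(T_min=10.0)
        retained, _ = apply_measurement_filters(_frame(T_meas=12.0), th)
        assert len(retained) == 1

    def test_idempotent_on_retained_set(self, standardised_cohort):
        from mesolim.simulate import inject_violations

        dirty = inject_violations(
            standardised_cohort, {"temperature": 0.1, "drawdown": 0.1}, seed=3
        )
        retained, _ = apply_measurement_filters(dirty)
        again, report = apply_measurement_filters(retained)
        assert len(again) == len(retained)
        assert not report.excluded_rows


class TestDetectOutliers:
    def test_extreme_thresholds_by_growth_form(self):
        flags = detect_outliers(
            [2.5, 1.5, 1.5], ["C3_annual_herb", "C3_annual_herb", "evergreen_angiosperm"]
        )
        # 2.5 > 2 flags the herb; 1.5 < 2 passes for the herb but > 1 flags the tree
        assert flags["reason"].tolist() == ["extreme", "", "extreme"]

    def test_fern_uses_woody_threshold(self):
        flags = detect_outliers([1.5, 0.05], ["fern", "fern"])
        assert flags["reason"].tolist() == ["extreme", ""]

    def test_all_equal_group_has_no_iqr_flags(self):
        flags = detect_outliers([0.2] * 4, ["fern"] * 4)
        assert not flags["outlier"].any()

    def test_iqr_flags_match_brute_force_oracle(self):
        values = [0.10, 0.12, 0.15, 0.20, 0.22, 0.25, 0.90]
        flags = detect_outliers(values, ["C3_annual_herb"] * 7)
        logv = np.log(values)
        q1, q3 = type7_quartiles(logv)
        iqr = q3 - q1
        expected = (logv < q1 - 1.5 * iqr) | (logv > q3 + 1.5 * iqr)
        assert flags["outlier"].tolist() == expected.tolist()
        assert flags["outlier"].sum() > 0  # the 0.90 point is an outlier

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.gamma(3.0, 0.05, 30)
        perm = rng.permutation(30)
        a = detect_outliers(values, ["fern"] * 30)["outlier"].to_numpy()
        b = detect_outliers(values[perm], ["fern"] * 30)["outlier"].to_numpy()
        assert np.array_equal(a[perm], b)

    def test_uniform_rescaling_preserves_iqr_flags(self):
        rng = np.random.default_rng(6)
        values = rng.gamma(3.0, 0.03, 40)  # well under the extreme threshold
        a = detect_outliers(values, ["evergreen_gymnosperm"] * 40)
        b = detect_outliers(values * 3.0, ["evergreen_gymnosperm"] * 40)
        iqr_a = a["reason"].to_numpy() == "iqr"
        iqr_b = b["reason"].to_numpy() == "iqr"
        assert np.array_equal(iqr_a, iqr_b)

    def test_small_group_skips_iqr_step(self):
        flags = detect_outliers([0.1, 0.2, 5e-5], ["fern"] * 3)
        assert not flags["outlier"].any()  # group of 3: step 2 skipped

    def test_steps_applied_in_order(self):
        # the extreme value must not enter the quartile computation
        values = [0.2, 0.21, 0.22, 0.23, 0.24, 3.0]
        flags = detect_outliers(values, ["C3_annual_herb"] * 6)
        assert flags["reason"].tolist()[:5] == [""] * 5
        assert flags["reason"].iloc[5] == "extreme"


class TestReconcileMethods:
    def test_curve_fitting_discarded(self):
        gm, rule = reconcile_methods([("curve_fitting", 0.20), ("isotope", 0.30)])
        assert gm == 0.30 and rule == "prefer_non_curve_fitting"

    def test_two_other_methods_averaged(self):
        gm, rule = reconcile_methods([("isotope", 0.20), ("fluorescence", 0.30)])
        assert gm == pytest.approx(0.25) and rule == "mean_of_two"

    def test_single_entry_identity(self):
        gm, rule = reconcile_methods([("fluorescence", 0.22)])
        assert gm == 0.22 and rule == "single"

    def test_beyond_rule_cases_warn_and_average(self):
        with pytest.warns(UserWarning):
            gm, rule = reconcile_methods(
                [("curve_fitting", 0.1), ("isotope", 0.2), ("fluorescence", 0.4)]
            )
        assert gm == pytest.approx(0.3) and rule == "mean_beyond_rules"

    def test_duplicate_methods_raise(self):
        with pytest.raises(ValueError):
            reconcile_methods([("isotope", 0.2), ("isotope", 0.3)])


class TestRunQc:
    def test_report_arithmetic_and_outlier_merge(self, standardised_cohort):
        df = standardised_cohort.copy()
        # plant one extreme value and one cold measurement
        df.loc[df.index[0], "gm_25"] = 5.0
        df.loc[df.index[1], "T_meas"] = 5.0
        retained, report = run_qc(df)
        assert report.n_input == len(df)
        assert report.n_input == report.n_retained + len(report.excluded_rows)
        assert report.n_excluded_by.get("outlier_extreme", 0) >= 1
        assert report.n_excluded_by["temperature"] >= 1
        assert df.index[0] not in retained.index
        assert df.index[1] not in retained.index

    def test_json_report_round_trip(self, standardised_cohort, tmp_path):
        import json

        _, report = run_qc(standardised_cohort)
        path = tmp_path / "qc.json"
        report.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["n_input"] == report.n_input
        assert doc["n_retained"] == report.n_retained
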