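"""Date calibration, PDF combination, and the observation filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paleoniche import chronology as chron
from paleoniche.chronology import (
    CalibrationCurve,
    DateMeasurement,
    DatedContext,
    NoDatesError,
    assign_and_filter,
    calibrate_radiocarbon,
    combine_dates,
    estimate_context_dates,
    pdf_from_absolute,
    round_to_millennium,
)
from paleoniche.synth import TrueNiche, generate_archaeological_record


def rc(age, err):
    return DateMeasurement("radiocarbon", age, err)


class TestCalibration:
    def test_identity_curve_returns_measurement_normal(self, identity_curve):
        pdf = calibrate_radiocarbon(rc(40_000, 100), identity_curve)
        expected = stats.norm.pdf(pdf.years, 40_000, 100)
        expected /= expected.sum()
        assert np.allclose(pdf.mass, expected, atol=1e-12)
        assert pdf.years[np.argmax(pdf.mass)] == 40_000

    def test_linear_curve_with_slope_two(self):
        cal = np.arange(0.0, 160_001.0, 10.0)
        curve = CalibrationCurve(cal_age=cal, c14_age=2 * cal, error=np.zeros_like(cal))
        pdf = calibrate_radiocarbon(rc(40_000, 100), curve)
        peak = pdf.years[np.argmax(pdf.mass)]
        assert peak == 20_000
        mean = float(pdf.mass @ pdf.years)
        sd = float(np.sqrt(pdf.mass @ (pdf.years - mean) ** 2))
        # the slope-2 curve halves the posterior spread: 100 / 2 = 50 yr
        assert abs(sd - 50.0) < 2.0

    def test_age_outside_curve_support_raises(self):
        cal = np.arange(0.0, 10_000.0, 10.0)
        curve = CalibrationCurve(cal_age=cal, c14_age=cal, error=np.full_like(cal, 10.0))
        with pytest.raises(chron.CalibrationRangeError):
            calibrate_radiocarbon(rc(60_000, 100), curve)

    def test_non_radiocarbon_method_rejected(self, identity_curve):
        with pytest.raises(ValueError):
            calibrate_radiocarbon(DateMeasurement("TL", 40_000, 100), identity_curve)


class TestAbsolutePDF:
    def test_mass_within_one_sigma_matches_normal_cdf(self):
        pdf = pdf_from_absolute(DateMeasurement("TL", 100_000, 1000))
        within = np.abs(pdf.years - 100_000) <= 1000
        expected = stats.norm.cdf(1) - stats.norm.cdf(-1)
        assert abs(pdf.mass[within].sum() - expected) < 5e-3
        assert pdf.years[np.argmax(pdf.mass)] == 100_000

    def test_near_delta_mass_concentrates(self):
        pdf = pdf_from_absolute(DateMeasurement("OSL", 100_000, 1.0), grid_step=1.0)
        within = np.abs(pdf.years - 100_000) <= 2
        assert pdf.mass[within].sum() > 0.98

    def test_deterministic(self):
        a = pdf_from_absolute(DateMeasurement("ESR", 80_000, 2500))
        b = pdf_from_absolute(DateMeasurement("ESR", 80_000, 2500))
        assert np.array_equal(a.mass, b.mass)

    @given(
        age=st.floats(min_value=5000, max_value=150_000),
        err=st.floats(min_value=50, max_value=5000),
    )
    @settings(max_examples=40, deadline=None)
    def test_masses_always_sum_to_one(self, age, err):
        pdf = pdf_from_absolute(DateMeasurement("U-series", age, err))
        assert abs(pdf.mass.sum() - 1.0) < 1e-9


class TestCombineDates:
    def test_single_normal_peak_and_confidence(self):
        res = combine_dates([pdf_from_absolute(DateMeasurement("TL", 100_000, 1000))])
        assert res.year_bp == 100_000
        expected = stats.norm.cdf(5) - stats.norm.cdf(-5)  # +-5000 yr = +-5 sigma
        assert abs(res.confidence - expected) < 1e-5
        assert res.millennium == 100_000

    def test_duplicate_pdfs_do_not_move_the_peak(self):
        p = pdf_from_absolute(DateMeasurement("TL", 100_000, 1000))
        one = combine_dates([p])
        two = combine_dates([p, p])
        assert one.year_bp == two.year_bp
        assert abs(one.confidence - two.confidence) < 1e-12

    def test_narrow_date_dominates_the_sum(self):
        narrow = pdf_from_absolute(DateMeasurement("OSL", 60_000, 500))
        wide = pdf_from_absolute(DateMeasurement("ESR", 70_000, 3000))
        res = combine_dates([narrow, wide])
        assert res.year_bp == 60_000

    def test_empty_input_raises(self):
        with pytest.raises(NoDatesError):
            combine_dates([])

    def test_confidence_monotone_in_window(self):
        pdfs = [pdf_from_absolute(DateMeasurement("TL", 90_000, 4000))]
        widths = [1000, 2000, 5000, 10_000]
        confs = [combine_dates(pdfs, window=w).confidence for w in widths]
        assert all(a <= b + 1e-12 for a, b in zip(confs, confs[1:]))

    def test_symmetric_unimodal_peak_at_common_mean(self):
        pdfs = [
            pdf_from_absolute(DateMeasurement("TL", 88_000, s)) for s in (800, 1500, 3000)
        ]
        assert combine_dates(pdfs).year_bp == 88_000

    def test_chronology_recovery_on_synthetic_records(self, static_world):
        niche = TrueNiche(weights={"temperature": 0.0, "precipitation": 0.0})
        contexts, truth = generate_archaeological_record(
            static_world,
            niche,
            60,
            dating_model={"TL": 1500.0, "OSL": 2000.0},
            dates_per_context=3.0,
            seed=21,
        )
        contexts = [c for c in contexts if len(c.measurements) >= 2]
        table = estimate_context_dates(contexts)
        merged = table.merge(truth, on="context_id")
        err = np.abs(merged["year_bp"] - merged["true_year"])
        assert np.median(err) < 1500


class TestMillenniumAndFilters:
    @pytest.mark.parametrize(
        "year,expected",
        [(100_499, 100_000), (100_501, 101_000), (100_500, 101_000), (50_000, 50_000)],
    )
    def test_nearest_millennium_half_toward_older(self, year, expected):
        assert round_to_millennium(year) == expected

    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "locality_id",
                "context_id",
                "longitude",
                "latitude",
                "year_bp",
                "confidence",
                "millennium",
                "n_dates",
                "peak_tied",
            ],
        )

    def test_duplicates_in_time_and_space_collapse(self):
        rows = [
            ["L1", f"C{i}", 10.0, 45.0, 80_000.0, 0.9, 80_000, 2, False] for i in range(3)
        ]
        filtered, report = assign_and_filter(self._table(rows))
        assert len(filtered) == 1
        assert report.n_duplicate == 2

    def test_filter_counts_are_additive(self):
        rows = [
            ["L1", "C1", 10.0, 45.0, 49_000.0, 0.9, 49_000, 1, False],   # too young
            ["L2", "C2", 10.0, 45.0, 150_000.0, 0.9, 150_000, 1, False], # too old
            ["L3", "C3", 75.0, 45.0, 80_000.0, 0.9, 80_000, 1, False],   # too far east
            ["L4", "C4", 10.0, 30.0, 80_000.0, 0.9, 80_000, 1, False],   # too far south
            ["L5", "C5", 10.0, 45.0, 80_000.0, 0.9, 80_000, 1, False],
            ["L5", "C6", 10.0, 45.0, 80_400.0, 0.9, 80_000, 1, False],   # duplicate
            ["L6", "C7", 12.0, 47.0, 90_000.0, 0.9, 90_000, 1, False],
        ]
        filtered, r = assign_and_filter(self._table(rows))
        assert (r.n_too_young, r.n_too_old, r.n_east, r.n_south, r.n_duplicate) == (1, 1, 1, 1, 1)
        assert r.n_retained == len(filtered) == 2
        assert r.n_retained + r.removed_total() == r.n_input

    def test_boundary_millennia_are_kept(self):
        rows = [
            ["L1", "C1", 10.0, 45.0, 50_000.0, 0.9, 50_000, 1, False],
            ["L2", "C2", 10.0, 45.0, 145_000.0, 0.9, 145_000, 1, False],
        ]
        filtered, _ = assign_and_filter(self._table(rows))
        assert len(filtered) == 2

    def test_contexts_without_dates_get_no_estimate(self, identity_curve):
        ctx = DatedContext("L1", "C1", 5.0, 45.0, measurements=[])
        table = estimate_context_dates([ctx], identity_curve)
        assert len(table) == 0
        assert table.attrs["n_without_dates"] == 1

    def test_mixed_method_context_combines_all_pdfs(self, identity_curve):
        ctx = DatedContext(
            "L1",
            "C1",
            5.0,
            45.0,
            measurements=[rc(45_000, 300), DateMeasurement("TL", 45_500, 3000)],
        )
        table = estimate_context_dates([ctx], identity_curve)
        assert table.loc[0, "n_dates"] == 2
        # the narrow radiocarbon date controls the peak
        assert abs(table.loc[0, "year_bp"] - 45_000) <= 100
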