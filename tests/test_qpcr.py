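"""Standard curves, primer QC gates, inverse interpolation, dynamic range."""
import itertools
import math

import numpy as np
import pytest

from zebrascreen.qpcr import (
    StandardCurve,
    StandardPoint,
    amplification_efficiency,
    dynamic_range_spacing,
    fit_standard_curve,
    interpolate_cell_count,
    primer_qc,
    quantify_unknowns,
    read_qpcr_table,
    standards_from_table,
)
from zebrascreen.synthetic import QpcrSimParams, simulate_qpcr

IDEAL_SLOPE = -1.0 / math.log10(2.0)  # perfect doubling, ~ -3.3219


def noise_free_points(slope=IDEAL_SLOPE, intercept=35.0, counts=(1e5, 1e4, 1e3, 1e2)):
    return [
        StandardPoint(c, (intercept + slope * math.log10(c),)) for c in counts
    ]


class TestFit:
    def test_noise_free_fit_recovers_truth(self):
        curve = fit_standard_curve(noise_free_points())
        assert curve.slope == pytest.approx(IDEAL_SLOPE, rel=1e-9)
        assert curve.intercept == pytest.approx(35.0, rel=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_standard_curve(noise_free_points(counts=(1e4, 1e3)))

    def test_identical_counts_error(self):
        pts = [StandardPoint(1000, (30.0,)) for _ in range(3)]
        with pytest.raises(ValueError, match="identical"):
            fit_standard_curve(pts)

    def test_zero_cell_negatives_excluded_from_fit(self):
        pts = noise_free_points() + [StandardPoint(0.0, (39.0,))]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(IDEAL_SLOPE, rel=1e-9)
        assert len(curve.points) == 5  # carried along, not fitted

    def test_replicates_match_preaveraged_fit(self, rng):
        counts = (1e5, 1e4, 1e3, 1e2)
        reps = [
            StandardPoint(c, tuple(30 - 3 * math.log10(c) + rng.normal(0, 0.3, 3)))
            for c in counts
        ]
        pre = [StandardPoint(c, (p.mean_ct,)) for c, p in zip(counts, reps)]
        a, b = fit_standard_curve(reps), fit_standard_curve(pre)
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_ct_range_validation(self):
        with pytest.raises(ValueError):
            StandardPoint(100, (0.0,))
        with pytest.raises(ValueError):
            StandardPoint(100, (46.0,))


class TestEfficiency:
    def test_perfect_doubling_is_100_percent(self):
        assert amplification_efficiency(IDEAL_SLOPE) == pytest.approx(100.0, abs=1e-9)

    def test_slope_minus_3_6(self):
        assert amplification_efficiency(-3.6) == pytest.approx(89.6, abs=0.05)

    def test_steep_slope_limit_is_zero(self):
        assert amplification_efficiency(-1e6) == pytest.approx(0.0, abs=1e-3)

    def test_nonnegative_slope_errors(self):
        with pytest.raises(ValueError):
            amplification_efficiency(0.0)


def _curve_with(slope, r_squared):
    return StandardCurve(
        slope=slope,
        intercept=35.0,
        r_squared=r_squared,
        points=tuple(noise_free_points(slope=slope)),
    )


def _slope_for_efficiency(eff_pct):
    return -1.0 / math.log10(1.0 + eff_pct / 100.0)


class TestPrimerQc:
    def test_passing_curve(self):
        v = primer_qc(_curve_with(-3.2, 0.99), n_melt_peaks=1)
        assert v.passed and v.reasons == ()

    def test_low_r_squared_itemized(self):
        v = primer_qc(_curve_with(-3.2, 0.85), n_melt_peaks=1)
        assert not v.passed
        assert any("R²" in r for r in v.reasons)

    def test_two_melt_peaks_itemized(self):
        v = primer_qc(_curve_with(-3.2, 0.99), n_melt_peaks=2)
        assert not v.passed
        assert any("melt" in r for r in v.reasons)

    def test_truth_table_on_boundary_grid(self):
        """Every gate combination over the boundary grid matches an
        independent re-statement of the rule.  Efficiency is a function of
        the slope, so the efficiency boundaries (89/90/120/121%) are
        exercised through the slopes that produce them."""
        slopes = [-3.4, -3.3, -3.2] + [
            _slope_for_efficiency(e) for e in (89, 90, 120, 121)
        ]
        for r2, slope, peaks in itertools.product(
            (0.89, 0.90, 0.91), slopes, (1, 2)
        ):
            v = primer_qc(_curve_with(slope, r2), n_melt_peaks=peaks)
            eff = (10 ** (-1 / slope) - 1) * 100
            expected = (
                r2 >= 0.9 and slope >= -3.3 and 90 <= eff <= 120 and peaks == 1
            )
            assert v.passed is expected, (r2, slope, eff, peaks)

    def test_efficiency_bounds_inclusive(self):
        # slopes nudged one ulp inside the boundary: exact 90/120% slopes
        # are not floating-point representable
        for eff, nudge in ((90, 1e-9), (120, -1e-9)):
            v = primer_qc(
                _curve_with(_slope_for_efficiency(eff) + nudge, 0.99), n_melt_peaks=1
            )
            assert v.checks["efficiency"], eff


class TestInterpolation:
    def test_ct_at_intercept_is_one_cell(self):
        curve = fit_standard_curve(noise_free_points())
        est = interpolate_cell_count(35.0, curve)
        assert est.cells == pytest.approx(1.0, rel=1e-9)
        assert est.extrapolated  # far below the calibrated range

    def test_thousand_cell_inoculum(self):
        curve = fit_standard_curve(noise_free_points())
        est = interpolate_cell_count(25.0343, curve)
        assert est.cells == pytest.approx(1000.0, rel=1e-3)
        assert not est.extrapolated

    def test_round_trip_is_exact_within_range(self):
        curve = fit_standard_curve(noise_free_points())
        for n in (150, 1000, 5e4):
            est = interpolate_cell_count(curve.predict_ct(n), curve)
            assert est.cells == pytest.approx(n, rel=1e-9)

    def test_failed_qc_blocks_unless_overridden(self):
        curve = _curve_with(-3.2, 0.5)
        primer_qc(curve, n_melt_peaks=1)
        with pytest.raises(ValueError, match="primer QC"):
            interpolate_cell_count(28.0, curve)
        with pytest.warns(UserWarning, match="failed primer QC"):
            interpolate_cell_count(28.0, curve, allow_failed_qc=True)


class TestDynamicRange:
    def test_tenfold_series_resolves_one_log_each(self):
        curve = fit_standard_curve(noise_free_points())
        spacing = dynamic_range_spacing(curve)
        assert spacing.separations == pytest.approx([1.0, 1.0, 1.0], rel=1e-9)
        assert spacing.mean == pytest.approx(1.0, rel=1e-9)

    def test_twofold_series_resolves_log10_two(self):
        counts = (8000, 4000, 2000, 1000)
        curve = fit_standard_curve(noise_free_points(counts=counts))
        spacing = dynamic_range_spacing(curve)
        assert spacing.mean == pytest.approx(math.log10(2), rel=1e-9)

    def test_noisy_simulated_curve_near_design_spacing(self):
        # 4-fold dilution designed spacing: log10(4) ~ 0.602
        df = simulate_qpcr(QpcrSimParams(noise_sd=0.2), seed=12)
        curve = fit_standard_curve(standards_from_table(df))
        spacing = dynamic_range_spacing(curve)
        assert spacing.mean == pytest.approx(math.log10(4), rel=0.10)

    def test_duplicate_standards_error(self):
        pts = [StandardPoint(c, (30.0 - i,)) for i, c in enumerate((1e3, 1e3, 1e4))]
        curve = fit_standard_curve(pts)
        with pytest.raises(ValueError, match="duplicate"):
            dynamic_range_spacing(curve)


class TestTableIo:
    def test_round_trip_through_csv(self, tmp_path):
        df = simulate_qpcr(QpcrSimParams(unknown_cells=(1000.0,)), seed=5)
        p = tmp_path / "qpcr.csv"
        df.to_csv(p, index=False)
        back = read_qpcr_table(p)
        pts = standards_from_table(back)
        # 5 positive standards; zero-cell negative has no determined Ct
        assert len(pts) == 5
        assert all(p.known_cells > 0 for p in pts)

    def test_undetermined_cts_become_missing(self, tmp_path):
        p = tmp_path / "qpcr.csv"
        p.write_text(
            "sample_id,role,template,known_cells,ct,melt_peaks\n"
            "S1,standard,gDNA,1000,25.1,1\n"
            "S1,standard,gDNA,1000,undetermined,1\n"
            "S2,standard,gDNA,100,,1\n"
        )
        df = read_qpcr_table(p)
        assert df["ct"].isna().sum() == 2
        with pytest.warns(UserWarning, match="S2"):
            pts = standards_from_table(df)
        assert len(pts) == 1 and pts[0].ct_values == (25.1,)

    def test_quantify_unknowns_reports_pool_and_average(self):
        df = simulate_qpcr(
            QpcrSimParams(noise_sd=0.0, unknown_cells=(1000.0,)), seed=1
        )
        curve = fit_standard_curve(standards_from_table(df))
        out = quantify_unknowns(df, curve, pool_size=10)
        assert len(out) == 1
        assert out.iloc[0]["cells_per_pool"] == pytest.approx(1000.0, rel=1e-9)
        assert out.iloc[0]["cells_per_embryo_avg"] == pytest.approx(100.0, rel=1e-9)
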