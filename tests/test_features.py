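"""Curve features: peak, slopes, fitted maximum, AUC, ratios, classification."""

import numpy as np
import pytest

from dcekit import (
    DCESeries,
    PipelineConfig,
    TissueMask,
    analyze_patient,
    auc_trapezoid,
    classify_curve,
    compute_features,
    contrast_ratios,
    detect_breakpoint,
    detect_peak,
    fit_slopes,
    fitted_maximum,
)
from dcekit.features import CurveFeatures, Line, round_report
from dcekit.tic import TimeIntensityCurve


def _curve(values, times=None, baseline_frames=None):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) if times is None else np.asarray(times, float)
    return TimeIntensityCurve("TSL", times, values, baseline_frames=baseline_frames)


class TestDetectPeak:
    def test_argmax_without_smoothing(self):
        assert detect_peak(_curve([1, 1, 3, 2, 2]), smooth_window=1) == 2

    def test_constant_curve_ties_to_earliest_frame(self):
        assert detect_peak(_curve([2, 2, 2, 2, 2])) == 0

    def test_window_must_be_shorter_than_curve(self):
        with pytest.raises(ValueError, match="smooth_window"):
            detect_peak(_curve([1, 2, 3, 2]), smooth_window=4)

    def test_modal_peak_under_noise(self):
        """200 noisy replicates of a curve peaking at frame 10 vote for 10."""
        frames = np.arange(30, dtype=float)
        truth = np.where(
            frames <= 10, 1 + 0.3 * frames, 4.0 - 0.1 * (frames - 10)
        )
        rng = np.random.default_rng(2024)
        peaks = [
            detect_peak(_curve(truth + rng.normal(0, 0.02, truth.size)))
            for _ in range(200)
        ]
        values, counts = np.unique(peaks, return_counts=True)
        assert values[np.argmax(counts)] == 10


class TestFitSlopes:
    def test_exact_ramps_recovered(self):
        curve = _curve([1, 2, 3, 4, 3.5, 3])
        wash_in, wash_out, degenerate = fit_slopes(curve, peak=3, onset=0)
        assert wash_in.slope == pytest.approx(1.0, abs=1e-12)
        assert wash_out.slope == pytest.approx(-0.5, abs=1e-12)
        assert not degenerate

    def test_plateau_after_peak_has_zero_slope(self):
        curve = _curve([1, 2, 4, 4, 4])
        _, wash_out, _ = fit_slopes(curve, peak=2, onset=0)
        assert wash_out.slope == pytest.approx(0.0, abs=1e-12)

    def test_peak_on_last_frame_degenerates_to_flat_washout(self):
        curve = _curve([1, 2, 3, 4])
        _, wash_out, degenerate = fit_slopes(curve, peak=3, onset=0)
        assert degenerate
        assert wash_out.slope == 0.0


class TestFittedMaximum:
    def test_closed_form_intersection(self):
        # slope 1 through (0,1); slope -0.2 through (10,3) -> y = 5 - 0.2 t
        value = fitted_maximum(Line(1.0, 1.0), Line(-0.2, 5.0))
        assert value == pytest.approx(1 + 10 / 3, rel=1e-12)

    def test_non_convergent_lines_return_none(self):
        assert fitted_maximum(Line(1.0, 0.0), Line(1.0, 0.0)) is None
        assert fitted_maximum(Line(0.1, 0.0), Line(0.5, -1.0)) is None

    def test_degenerate_curve_falls_back_to_observed_max(self):
        # monotone decline: wash-in fit is negative, flagged and bounded
        feats = compute_features(_curve([4, 3, 2, 1, 0.5]))
        assert feats.degenerate
        assert feats.fitted_maximum == 4.0


class TestAUC:
    def test_constant_curve(self):
        assert auc_trapezoid(_curve(np.ones(10))) == pytest.approx(9.0)

    def test_unit_triangle(self):
        assert auc_trapezoid(_curve([0, 1, 0])) == pytest.approx(1.0)

    def test_against_fine_rectangle_sum(self):
        """Trapezoid on piecewise-linear input equals dense rectangle sums."""
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 10, 12))
        values = rng.uniform(0, 4, 12)
        fine_t = np.linspace(times[0], times[-1], 200_001)
        fine_v = np.interp(fine_t, times, values)
        riemann = np.sum((fine_v[:-1] + fine_v[1:]) / 2 * np.diff(fine_t))
        assert auc_trapezoid(_curve(values, times)) == pytest.approx(
            riemann, abs=1e-6
        )


class TestClassify:
    @pytest.mark.parametrize(
        "slope, expected",
        [(0.63, "persistent"), (0.0, "plateau"), (-0.5, "washout"),
         (0.009, "plateau"), (-0.011, "washout")],
    )
    def test_washout_slope_sign_rules(self, slope, expected):
        assert classify_curve(slope, epsilon=0.01) == expected


def _feats(tissue, wash_in, wash_out, fmax):
    return CurveFeatures(
        tissue=tissue, wash_in_slope=wash_in, wash_out_slope=wash_out,
        fitted_maximum=fmax, max_value=fmax, time_to_peak=5.0, auc=10.0,
        curve_type="washout", fit_window_in=(1, 5), fit_window_out=(5, 9),
    )


class TestContrastRatios:
    def test_reported_fmcr_cells(self):
        """Ratios of cohort fitted maxima round to the reported fMCR cells."""
        feats = {
            "TSL": _feats("TSL", 1.0, -0.1, 4.22),
            "PLT": _feats("PLT", 0.5, -0.1, 2.16),
        }
        assert round_report(contrast_ratios(feats, ("TSL", "PLT")).fmcr) == 1.95
        feats = {
            "TSL": _feats("TSL", 1.0, -0.1, 1.46),
            "NAT": _feats("NAT", 0.5, -0.1, 0.98),
        }
        assert round_report(contrast_ratios(feats, ("TSL", "NAT")).fmcr) == 1.49

    def test_tissue_against_itself_is_unity(self):
        feats = {"TSL": _feats("TSL", 1.0, -0.1, 4.0)}
        ratios = contrast_ratios({"TSL": feats["TSL"], "X": feats["TSL"]}, ("TSL", "X"))
        assert ratios.wash_in_ratio == ratios.wash_out_ratio == ratios.fmcr == 1.0

    def test_negative_washout_sign_propagates(self):
        feats = {
            "TSL": _feats("TSL", 1.0, -0.12, 3.0),
            "NAT": _feats("NAT", 0.5, 0.10, 1.0),
        }
        assert contrast_ratios(feats, ("TSL", "NAT")).wash_out_ratio < 0

    def test_zero_denominator_is_informative(self):
        feats = {
            "TSL": _feats("TSL", 1.0, -0.1, 3.0),
            "NAT": _feats("NAT", 0.0, 0.1, 1.0),
        }
        with pytest.raises(ZeroDivisionError, match="wash_in_slope"):
            contrast_ratios(feats, ("TSL", "NAT"))


class TestPhantomRecovery:
    def test_noiseless_recovery_is_exact(self, phantom_result):
        """Slopes and fitted maxima match the generating kinetics to 1e-9."""
        result, gt = phantom_result
        for tissue, kin in gt.items():
            f = result["features"][tissue]
            assert f.wash_in_slope == pytest.approx(kin.wash_in_slope, abs=1e-9)
            assert f.wash_out_slope == pytest.approx(kin.wash_out_slope, abs=1e-9)
            assert f.fitted_maximum == pytest.approx(kin.apex_value, abs=1e-9)
            assert f.curve_type == kin.curve_type
            assert not f.degenerate

    def test_breakpoint_detection_finds_persistent_knee(self, noiseless_phantom):
        _, series, mask, gt = noiseless_phantom
        from dcekit import extract_curve, normalize_baseline

        curve = normalize_baseline(extract_curve(series, mask, "NAT"), 2)
        assert detect_breakpoint(curve, onset=1) == gt["NAT"].peak_frame

    def test_noisy_recovery_median_error_under_ten_percent(self, noisy_slope_errors):
        for name, errors in noisy_slope_errors.items():
            assert np.median(errors) < 0.10, name

    def test_contrast_ratios_invariant_to_global_scaling(self, noiseless_phantom):
        _, series, mask, _ = noiseless_phantom
        config = PipelineConfig()
        base = analyze_patient(series, mask, config)
        scaled_series = DCESeries(series.data * 7.3, series.frame_times)
        scaled = analyze_patient(scaled_series, TissueMask(mask.labels, mask.label_map), config)
        for pair in base["ratios"]:
            assert scaled["ratios"][pair].fmcr == pytest.approx(
                base["ratios"][pair].fmcr, rel=1e-9
            )
            assert scaled["ratios"][pair].wash_in_ratio == pytest.approx(
                base["ratios"][pair].wash_in_ratio, rel=1e-9
            )
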