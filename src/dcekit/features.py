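"""Semi-quantitative DCE curve features and tissue contrast ratios.

The analytical core of the pipeline.  A baseline-normalized time-intensity
curve is decomposed into a *wash-in* line (least-squares fit from the end of
the baseline to the enhancement peak) and a *wash-out* line (fit from the
peak to the last frame).  The intensity at the intersection of the two
lines is the *fitted maximum*; the ratio of two tissues' fitted maxima is
the *fitted maximum contrast ratio* (fMCR), the headline statistic for
discriminating tumor-suspicious lesions (TSL) from perilesional (PLT) and
normal-appearing (NAT) tissue.  Curves are also classified into the classic
enhancement archetypes: persistent rise (type 1), plateau (type 2), and
rapid washout (type 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tic import TimeIntensityCurve

__all__ = [
    "Line",
    "CurveFeatures",
    "TissueContrast",
    "detect_peak",
    "detect_breakpoint",
    "fit_slopes",
    "fitted_maximum",
    "auc_trapezoid",
    "classify_curve",
    "compute_features",
    "contrast_ratios",
    "round_report",
]

#: Default tolerance (normalized units per time unit) separating plateau
#: from persistent/washout wash-out slopes.
PLATEAU_EPSILON = 0.01


@dataclass(frozen=True)
class Line:
    """A fitted line ``y = slope * t + intercept`` in curve time units."""

    slope: float
    intercept: float

    def __call__(self, t: float) -> float:
        return self.slope * t + self.intercept


@dataclass(frozen=True)
class CurveFeatures:
    tissue: str
    wash_in_slope: float
    wash_out_slope: float
    fitted_maximum: float
    max_value: float
    time_to_peak: float
    auc: float
    curve_type: str
    fit_window_in: tuple[int, int]
    fit_window_out: tuple[int, int]
    degenerate: bool = False


@dataclass(frozen=True)
class TissueContrast:
    """Dimensionless ratios between a numerator and a denominator tissue."""

    pair: tuple[str, str]
    wash_in_ratio: float
    wash_out_ratio: float
    fmcr: float

    @property
    def name(self) -> str:
        return f"{self.pair[0]}/{self.pair[1]}"


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    # centered smoothing; edges use the shrinking-window mean
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + values.size]
    return out


def detect_peak(curve: TimeIntensityCurve, smooth_window: int = 1) -> int:
    """Frame index of the curve maximum after optional moving-average smoothing.

    Ties break toward the earliest frame, so a flat curve peaks at frame 0.
    """
    if len(curve) < 4:
        raise ValueError("curve too short for peak detection (need >= 4 frames)")
    if smooth_window >= len(curve):
        raise ValueError(
            f"smooth_window {smooth_window} must be < curve length {len(curve)}"
        )
    smoothed = _moving_average(curve.values, smooth_window)
    return int(np.argmax(smoothed))  # argmax takes the first maximum


def detect_breakpoint(curve: TimeIntensityCurve, onset: int = 0) -> int:
    """Wash-in/wash-out transition frame by two-segment least squares.

    For a persistently rising (type 1) curve the global maximum sits on the
    last frame, which leaves no wash-out window; the transition the line
    intersection refers to is then the *knee* where the steep wash-in ramp
    gives way to the shallow late slope.  This picks the breakpoint ``b``
    minimizing the summed squared residuals of the two OLS lines fit on
    ``[onset, b]`` and ``[b, end]``, ties toward the earliest frame.  On a
    noiseless piecewise-linear curve the true knee gives zero residual, so
    recovery is exact.
    """
    t, y = curve.times, curve.values
    n = len(curve)
    lo = max(onset + 1, 1)
    if lo > n - 2:
        raise ValueError("curve too short for breakpoint detection")

    def sse(i: int, j: int) -> float:
        coeffs = np.polyfit(t[i : j + 1], y[i : j + 1], 1)
        resid = y[i : j + 1] - np.polyval(coeffs, t[i : j + 1])
        return float(resid @ resid)

    costs = [sse(onset, b) + sse(b, n - 1) for b in range(lo, n - 1)]
    return lo + int(np.argmin(costs))


def fit_slopes(
    curve: TimeIntensityCurve, peak: int, onset: int = 0
) -> tuple[Line, Line, bool]:
    """Least-squares wash-in and wash-out lines around the peak.

    The wash-in line is fit on frames ``[onset, peak]`` (onset = the last
    baseline frame), the wash-out line on ``[peak, end]``; the peak frame
    belongs to both windows.  Returns ``(wash_in, wash_out, degenerate)``.

    Degenerate windows (fewer than two points) fall back conservatively:
    a missing wash-in window widens to ``[0, peak]``, and a peak on the
    last frame yields a flat wash-out line through the peak value; both
    set the degenerate flag.
    """
    t, y = curve.times, curve.values
    degenerate = False
    lo = min(onset, peak)
    if peak - lo < 1:  # widen toward frame 0, flag if still too short
        lo = 0
        degenerate = True
    if peak - lo >= 1:
        m, b = np.polyfit(t[lo : peak + 1], y[lo : peak + 1], 1)
        wash_in = Line(float(m), float(b))
    else:
        degenerate = True
        wash_in = Line(0.0, float(y[peak]))
    if len(curve) - peak >= 2:
        m, b = np.polyfit(t[peak:], y[peak:], 1)
        wash_out = Line(float(m), float(b))
    else:  # peak at the last frame: no wash-out window
        degenerate = True
        wash_out = Line(0.0, float(y[peak]))
    return wash_in, wash_out, degenerate


def fitted_maximum(wash_in: Line, wash_out: Line) -> float | None:
    """Intensity at the intersection of the wash-in and wash-out lines.

    Returns ``None`` when the lines do not converge forward in time
    (wash-in slope <= wash-out slope); the caller substitutes the observed
    maximum and flags the curve as degenerate.
    """
    if wash_in.slope <= wash_out.slope:
        return None
    t_star = (wash_out.intercept - wash_in.intercept) / (
        wash_in.slope - wash_out.slope
    )
    return float(wash_in(t_star))


def auc_trapezoid(curve: TimeIntensityCurve) -> float:
    """Trapezoidal area under the curve, in normalized intensity x time."""
    if len(curve) < 2:
        raise ValueError("AUC needs at least 2 points")
    return float(np.trapezoid(curve.values, curve.times))


def classify_curve(wash_out_slope: float, epsilon: float = PLATEAU_EPSILON) -> str:
    """Enhancement archetype from the wash-out slope sign.

    persistent (type 1) if slope > epsilon, plateau (type 2) within
    +-epsilon, washout (type 3) if slope < -epsilon.
    """
    if wash_out_slope > epsilon:
        return "persistent"
    if wash_out_slope < -epsilon:
        return "washout"
    return "plateau"


def compute_features(
    curve: TimeIntensityCurve,
    smooth_window: int = 1,
    epsilon: float = PLATEAU_EPSILON,
    onset: int | None = None,
) -> CurveFeatures:
    """Full semi-quantitative feature set for one normalized curve.

    ``onset`` defaults to the last baseline frame of a normalized curve
    (``baseline_frames - 1``) and to frame 0 for a raw curve.

    The peak is the smoothed-curve maximum; when that maximum falls on the
    last frame (a persistently rising curve, leaving no wash-out window)
    the wash-in/wash-out transition is located instead by two-segment
    least squares (:func:`detect_breakpoint`).
    """
    if onset is None:
        onset = (curve.baseline_frames - 1) if curve.is_normalized else 0
    peak = detect_peak(curve, smooth_window=smooth_window)
    if peak >= len(curve) - 1:
        peak = detect_breakpoint(curve, onset=onset)
    wash_in, wash_out, degenerate = fit_slopes(curve, peak, onset=onset)
    fmax = fitted_maximum(wash_in, wash_out)
    max_value = float(np.max(curve.values))
    if fmax is None:
        fmax = max_value
        degenerate = True
    return CurveFeatures(
        tissue=curve.tissue,
        wash_in_slope=wash_in.slope,
        wash_out_slope=wash_out.slope,
        fitted_maximum=fmax,
        max_value=max_value,
        time_to_peak=float(curve.times[peak] - curve.times[0]),
        auc=auc_trapezoid(curve),
        curve_type=classify_curve(wash_out.slope, epsilon),
        fit_window_in=(min(onset, peak), peak),
        fit_window_out=(peak, len(curve) - 1),
        degenerate=degenerate,
    )


def contrast_ratios(
    features_by_tissue: dict[str, CurveFeatures], pair: tuple[str, str]
) -> TissueContrast:
    """Ratios of the pair's wash-in slopes, wash-out slopes and fitted maxima.

    Ratios keep full precision internally; use :func:`round_report` when
    printing.  Wash-out ratios carry the sign of the operands (a negative
    tumor wash-out over a positive reference wash-out is negative).
    """
    num, den = pair
    for tissue in pair:
        if tissue not in features_by_tissue:
            raise KeyError(f"no features for tissue {tissue!r}")
    f_num, f_den = features_by_tissue[num], features_by_tissue[den]
    for quantity, value in [
        ("wash_in_slope", f_den.wash_in_slope),
        ("wash_out_slope", f_den.wash_out_slope),
        ("fitted_maximum", f_den.fitted_maximum),
    ]:
        if value == 0:
            raise ZeroDivisionError(
                f"denominator tissue {den!r} has zero {quantity}"
            )
    return TissueContrast(
        pair=pair,
        wash_in_ratio=f_num.wash_in_slope / f_den.wash_in_slope,
        wash_out_ratio=f_num.wash_out_slope / f_den.wash_out_slope,
        fmcr=f_num.fitted_maximum / f_den.fitted_maximum,
    )


def round_report(value: float, decimals: int = 2) -> float:
    """Half-to-even rounding used for all printed report values."""
    return float(np.round(value, decimals))
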