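"""Transit-time estimation and pulse wave velocity.

Three landmark algorithms, applied to the ascending and descending curves of a
:class:`~pwvkit.curves.CurvePair`:

``TTF`` (time-to-foot)
    Intersection with the (baseline-corrected) zero line of the tangent drawn
    at the point of maximum systolic upslope.  The only method that references
    the baseline, hence the only one to which baseline correction applies.
``max_upslope``
    Time of the maximum discrete derivative between cycle start and the global
    maximum.
``TTP`` (time-to-peak)
    Time of the global curve maximum.

PWV = Δd / Δt with Δd in mm and Δt in ms, so the ratio is directly in m/s.
Δt may be negative (curves with no definitive peak can place the descending
landmark before the ascending one); Δt = 0 leaves PWV undefined and flagged
rather than infinite.

All curves are Gaussian-smoothed before landmark detection.  The smoothing SD
is specified as a fraction of the cardiac cycle (default 0.025) and converted
to samples per curve, which makes the filter independent of temporal
resolution — the same setting applies to a 44-frame acquisition and a
10,000-frame phantom curve.  Smoothing and all shifts are circular: the
reconstructed cycle is periodic under retrospective gating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .curves import CurvePair, SampledCurve
from .errors import AnalysisError, ParameterError, UndefinedPWVError

TransitMethod = Literal["TTF", "max_upslope", "TTP"]
BaselineMode = Literal["none", "automatic", "manual"]

#: Phase window of the automatic baseline: late diastole, 80th–95th percent of
#: the cycle, far from the systolic upslope and late enough to dodge most
#: early-diastolic retrograde flow.
AUTO_BASELINE_WINDOW = (0.80, 0.95)


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing with SD expressed as a fraction of the cycle."""

    sigma_cycle_fraction: float = 0.025
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled and not self.sigma_cycle_fraction > 0:
            raise ParameterError("sigma_cycle_fraction must be positive when enabled")


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline correction mode; manual mode needs a phase window [a, b)."""

    mode: BaselineMode = "none"
    manual_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "automatic", "manual"):
            raise ParameterError(f"unknown baseline mode {self.mode!r}")
        if self.mode == "manual":
            if self.manual_window is None:
                raise ParameterError("manual baseline correction requires manual_window")
            a, b = self.manual_window
            if not (0 <= a < b <= 1):
                raise ParameterError("manual_window must satisfy 0 <= a < b <= 1")


@dataclass(frozen=True)
class TransitEstimate:
    """Result of one transit-time measurement on a curve pair."""

    method: TransitMethod
    baseline: BaselineSpec
    delta_t_ms: float
    landmark_asc_ms: float
    landmark_desc_ms: float
    pwv_m_per_s: float | None   # None when delta_t is zero (undefined, flagged)
    delta_d_mm: float
    n_frames: int
    cycle_duration_ms: float

    @property
    def pwv_defined(self) -> bool:
        return self.pwv_m_per_s is not None


def smooth_curve(curve: SampledCurve, spec: SmoothingSpec = SmoothingSpec()) -> SampledCurve:
    """Circular Gaussian smoothing; conserves the curve mean exactly."""
    if not spec.enabled:
        return curve
    sigma_samples = spec.sigma_cycle_fraction * curve.n_frames
    smoothed = gaussian_filter1d(curve.values, sigma_samples, mode="wrap")
    return curve.with_values(smoothed)


def _window_indices(n_frames: int, a: float, b: float) -> np.ndarray:
    idx = np.arange(n_frames)
    mask = (idx / n_frames >= a) & (idx / n_frames < b)
    return idx[mask]


def baseline_correct(curve: SampledCurve, spec: BaselineSpec) -> SampledCurve:
    """Subtract the mean of the baseline-defining window (per curve).

    Automatic mode uses the late-diastolic 80th–95th % segment of the cycle
    (half-open in phase: samples with 0.80 <= i/n < 0.95); manual mode uses the
    caller-supplied window, typically the segment just before the systolic
    upslope.
    """
    if spec.mode == "none":
        return curve
    a, b = AUTO_BASELINE_WINDOW if spec.mode == "automatic" else spec.manual_window
    idx = _window_indices(curve.n_frames, a, b)
    if idx.size == 0:
        raise AnalysisError(
            f"baseline window [{a}, {b}) contains no samples at n_frames={curve.n_frames}"
        )
    return curve.with_values(curve.values - curve.values[idx].mean())


def _discrete_derivative(values: np.ndarray, frame_ms: float) -> np.ndarray:
    """Central difference in units per ms; one-sided at the array boundary."""
    d = np.empty_like(values)
    d[1:-1] = (values[2:] - values[:-2]) / (2.0 * frame_ms)
    d[0] = (values[1] - values[0]) / frame_ms
    d[-1] = (values[-1] - values[-2]) / frame_ms
    return d


def _landmark_ms(curve: SampledCurve, method: TransitMethod,
                 baseline: BaselineSpec, smoothing: SmoothingSpec) -> float:
    """Landmark time in ms for one curve after smoothing (+ TTF baseline)."""
    smoothed = smooth_curve(curve, smoothing)
    if method == "TTF":
        smoothed = baseline_correct(smoothed, baseline)
    values = smoothed.values
    frame_ms = curve.frame_duration_ms

    i_peak = int(np.argmax(values))  # earliest frame on ties (argmax contract)
    if method == "TTP":
        return i_peak * frame_ms

    deriv = _discrete_derivative(values, frame_ms)
    # Systolic upslope lives between cycle start and the global maximum.
    i_up = int(np.argmax(deriv[: i_peak + 1]))
    slope = deriv[i_up]
    if slope <= 0:
        raise AnalysisError("no positive upslope found (flat or degenerate curve)")
    if method == "max_upslope":
        return i_up * frame_ms
    # TTF: zero-crossing of the tangent through (t_up, y(t_up)) with slope s.
    t_up = i_up * frame_ms
    return t_up - values[i_up] / slope


def transit_time(pair: CurvePair, method: TransitMethod,
                 baseline: BaselineSpec = BaselineSpec(mode="automatic"),
                 smoothing: SmoothingSpec = SmoothingSpec(),
                 unwrap: bool = False) -> TransitEstimate:
    """Estimate transit time Δt and PWV for one curve pair.

    Baseline correction only applies to TTF (the only baseline-dependent
    landmark); for the other methods it is forced to ``none``.  With
    ``unwrap=True`` a Δt below −cycle/2 is shifted up by one cycle (circular
    ambiguity); default off — negative transit times are reported as-is.
    """
    if method not in ("TTF", "max_upslope", "TTP"):
        raise ParameterError(f"unknown transit method {method!r}")
    effective_baseline = baseline if method == "TTF" else BaselineSpec(mode="none")
    t_asc = _landmark_ms(pair.ascending, method, effective_baseline, smoothing)
    t_desc = _landmark_ms(pair.descending, method, effective_baseline, smoothing)
    delta_t = t_desc - t_asc
    if unwrap and delta_t < -pair.cycle_duration_ms / 2:
        delta_t += pair.cycle_duration_ms
    try:
        pwv = compute_pwv(pair.delta_d_mm, delta_t)
    except UndefinedPWVError:
        pwv = None
    return TransitEstimate(
        method=method, baseline=effective_baseline, delta_t_ms=delta_t,
        landmark_asc_ms=t_asc, landmark_desc_ms=t_desc, pwv_m_per_s=pwv,
        delta_d_mm=pair.delta_d_mm, n_frames=pair.n_frames,
        cycle_duration_ms=pair.cycle_duration_ms,
    )


def compute_pwv(delta_d_mm: float, delta_t_ms: float) -> float:
    """PWV = Δd / Δt; mm over ms is numerically equal to m/s.  Signed."""
    if delta_t_ms == 0:
        raise UndefinedPWVError("transit time is zero; PWV undefined")
    return delta_d_mm / delta_t_ms


def temporal_resolution_ms(heart_rate_bpm: float, timeframes: int) -> float:
    """Temporal resolution: heartbeat duration divided by timeframes per cycle."""
    if heart_rate_bpm <= 0 or timeframes <= 0:
        raise ParameterError("heart rate and timeframes must be positive")
    return 60000.0 / (heart_rate_bpm * timeframes)


def temporal_resolution_rounded_ms(heart_rate_bpm: float, timeframes: int) -> int:
    """Temporal resolution rounded to the nearest ms, half away from zero."""
    x = temporal_resolution_ms(heart_rate_bpm, timeframes)
    return int(math.floor(x + 0.5))
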