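"""Temporal-resolution computer phantom.

The experiment asks: how many timeframes per cardiac cycle does a
phase-contrast acquisition need before transit-time PWV becomes accurate?

Construction, for one reference PWV and one vessel length:

1. take a high-resolution ascending waveform (10,000 timeframes per cycle);
2. create the descending curve by circularly delaying the ascending one by
   ``length / PWV`` (mm over m/s gives ms) and scaling its amplitude by 0.6
   (blood diverted into the aortic arch branches);
3. apply a Gaussian smoothing filter of width 2,000 timeframes (interpreted as
   total kernel support, SD = width/6 — see ``smooth_width_semantics``);
4. downsample both curves to 20–60 timeframes per cycle by periodic linear
   interpolation, mimicking acquisition at discrete timeframes;
5. estimate PWV with time-to-foot + automatic baseline correction and report
   the signed % error against the reference.

By default the smoothing filter is applied to *both* curves.  Smoothing
commutes with the circular shift, so the smoothed pair is still an exactly
delayed pair and the only error source is temporal discretization — which is
the quantity under study.  Smoothing only the shifted copy
(``smooth_target="descending"``) is also available; it widens one upslope
relative to the other and adds a constant foot-detection offset of a few ms to
every Δt, i.e. a resolution-independent bias on top of the discretization
error.

The required-timeframes cut-off is the smallest grid resolution N such that
|% error| stays within tolerance for every reference PWV at every N' ≥ N
(default tolerance 10 %).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .curves import CurvePair, SampledCurve
from .errors import AnalysisError, ConstructionError, ParameterError
from .transit import BaselineSpec, SmoothingSpec, transit_time

#: Paper-style default grids.
DEFAULT_REF_PWV = (2.0, 4.0, 6.0, 8.0, 10.0)
DEFAULT_FRAMES_GRID = tuple(range(20, 61))
#: Vessel lengths studied per profile: shortest aortic arch and thoracic aorta
#: in each group (mm).
PROFILE_LENGTHS_MM = {"neonate": (25.0, 60.0), "adolescent": (60.0, 150.0)}
ALL_LENGTHS_MM = (25.0, 60.0, 150.0)


def upsample(curve: SampledCurve, target_frames: int) -> SampledCurve:
    """Periodic linear interpolation onto a finer uniform phase grid."""
    if target_frames < curve.n_frames:
        raise ParameterError("target_frames must not be smaller than the source")
    return _resample(curve, target_frames)


def downsample(curve: SampledCurve, n_frames: int) -> SampledCurve:
    """Point-sample the curve at n coarser acquisition phases (periodic)."""
    if n_frames > curve.n_frames:
        raise ParameterError("n_frames must not exceed the source resolution")
    if n_frames < 8:
        raise ParameterError("n_frames must be at least 8")
    return _resample(curve, n_frames)


def _resample(curve: SampledCurve, n: int, phase_offset: float = 0.0) -> SampledCurve:
    src = curve.values
    m = curve.n_frames
    xp = np.arange(m + 1) / m                      # closed periodic grid
    fp = np.concatenate([src, src[:1]])
    phases = (np.arange(n) / n + phase_offset) % 1.0
    return curve.with_values(np.interp(phases, xp, fp))


def circular_shift(curve: SampledCurve, delay_ms: float) -> SampledCurve:
    """Delay the curve by ``delay_ms`` with periodic linear interpolation."""
    n = curve.n_frames
    src = curve.values
    xp = np.arange(n + 1) / n
    fp = np.concatenate([src, src[:1]])
    phases = (np.arange(n) / n - delay_ms / curve.cycle_duration_ms) % 1.0
    return curve.with_values(np.interp(phases, xp, fp))


@dataclass(frozen=True)
class PhantomSpec:
    """Definition of one temporal-resolution experiment (one vessel length)."""

    base_curve: SampledCurve
    vessel_length_mm: float = 60.0
    ref_pwv_grid: Sequence[float] = DEFAULT_REF_PWV
    frames_grid: Sequence[int] = DEFAULT_FRAMES_GRID
    upsample_frames: int = 10000
    desc_scale: float = 0.6
    smooth_width_frames: float = 2000.0   # 0 disables the smoothing step
    #: "support": kernel support = width, SD = width/6 (±3 SD inside the window);
    #: "sd": width is the Gaussian SD itself.
    smooth_width_semantics: Literal["support", "sd"] = "support"
    #: Which curve(s) receive the phantom smoothing filter.
    smooth_target: Literal["both", "descending"] = "both"
    #: Phase origin of the downsampling grid (sensitivity probe; default 0).
    downsample_phase_offset: float = 0.0
    tolerance_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.upsample_frames < max(self.frames_grid):
            raise ParameterError("upsample_frames must cover the frames grid")
        if any(p <= 0 for p in self.ref_pwv_grid):
            raise ParameterError("reference PWV values must be positive")
        if not 0 < self.desc_scale <= 1:
            raise ParameterError("desc_scale must lie in (0, 1]")
        if not self.vessel_length_mm > 0:
            raise ParameterError("vessel_length_mm must be positive")
        cycle = self.base_curve.cycle_duration_ms
        worst = self.vessel_length_mm / min(self.ref_pwv_grid)
        if worst >= cycle:
            raise ConstructionError(
                f"delay {worst:.0f} ms for the slowest reference PWV is not shorter "
                f"than the cycle ({cycle:.0f} ms)"
            )

    @property
    def smooth_sigma_frames(self) -> float:
        if self.smooth_width_semantics == "sd":
            return self.smooth_width_frames
        return self.smooth_width_frames / 6.0


@dataclass(frozen=True)
class ErrorGrid:
    """%-error matrix over (reference PWV × timeframes) with its cut-off."""

    errors_pct: np.ndarray                 # shape (len(ref_pwv), len(frames))
    ref_pwv_grid: tuple[float, ...]
    frames_grid: tuple[int, ...]
    tolerance_pct: float
    cutoff_frames: int | None              # None when no resolution satisfies it
    post_cutoff_error_range_pct: tuple[float, float] | None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: ref_pwv_m_per_s, n_frames, error_pct."""
        rows = [
            (p, n, self.errors_pct[i, j])
            for i, p in enumerate(self.ref_pwv_grid)
            for j, n in enumerate(self.frames_grid)
        ]
        return pd.DataFrame(rows, columns=["ref_pwv_m_per_s", "n_frames", "error_pct"])


def build_phantom_pair(spec: PhantomSpec, ref_pwv: float) -> CurvePair:
    """High-resolution delayed/scaled/smoothed pair for one reference PWV."""
    delay_ms = spec.vessel_length_mm / ref_pwv
    base = upsample(spec.base_curve, spec.upsample_frames)
    if delay_ms >= base.cycle_duration_ms:
        raise ConstructionError(
            f"delay {delay_ms:.1f} ms is not shorter than the cycle "
            f"({base.cycle_duration_ms:.1f} ms)"
        )
    desc = circular_shift(base, delay_ms)
    desc = desc.with_values(spec.desc_scale * desc.values, label="descending")
    asc = base.with_values(base.values, label="ascending")
    sigma = spec.smooth_sigma_frames
    if sigma > 0:
        desc = desc.with_values(gaussian_filter1d(desc.values, sigma, mode="wrap"))
        if spec.smooth_target == "both":
            asc = asc.with_values(gaussian_filter1d(asc.values, sigma, mode="wrap"))
    return CurvePair(ascending=asc, descending=desc,
                     delta_d_mm=spec.vessel_length_mm,
                     construction_delay_ms=delay_ms)


def estimate_pwv_ttf(pair: CurvePair, n_frames: int | None = None,
                     phase_offset: float = 0.0) -> float | None:
    """TTF + automatic baseline PWV, optionally after downsampling to n frames."""
    if n_frames is not None and n_frames != pair.n_frames:
        pair = CurvePair(
            ascending=_resample(pair.ascending, n_frames, phase_offset),
            descending=_resample(pair.descending, n_frames, phase_offset),
            delta_d_mm=pair.delta_d_mm,
            construction_delay_ms=pair.construction_delay_ms,
        )
    est = transit_time(pair, "TTF", BaselineSpec(mode="automatic"), SmoothingSpec())
    return est.pwv_m_per_s


def run_resolution_experiment(spec: PhantomSpec) -> ErrorGrid:
    """%-error of TTF PWV over the (reference PWV × timeframes) grid.

    Deterministic given the base curve.  Cells where the analysis fails (e.g.
    no definable upslope at very coarse sampling) are recorded as NaN, never
    as silent zeros.
    """
    errors = np.full((len(spec.ref_pwv_grid), len(spec.frames_grid)), np.nan)
    for i, ref_pwv in enumerate(spec.ref_pwv_grid):
        pair = build_phantom_pair(spec, ref_pwv)
        for j, n in enumerate(spec.frames_grid):
            try:
                pwv = estimate_pwv_ttf(pair, n, spec.downsample_phase_offset)
            except AnalysisError:
                continue
            if pwv is not None:
                errors[i, j] = (pwv - ref_pwv) / ref_pwv * 100.0
    cutoff, err_range = find_required_frames(
        errors, spec.frames_grid, spec.tolerance_pct)
    return ErrorGrid(errors_pct=errors, ref_pwv_grid=tuple(spec.ref_pwv_grid),
                     frames_grid=tuple(int(n) for n in spec.frames_grid),
                     tolerance_pct=spec.tolerance_pct, cutoff_frames=cutoff,
                     post_cutoff_error_range_pct=err_range)


def find_required_frames(errors_pct: np.ndarray, frames_grid: Sequence[int],
                         tolerance_pct: float
                         ) -> tuple[int | None, tuple[float, float] | None]:
    """Smallest N with |error| ≤ tolerance for all reference PWV at all N' ≥ N.

    Returns ``(cutoff, (min_error, max_error))`` over the at-and-beyond-cutoff
    region, or ``(None, None)`` when no resolution satisfies the criterion
    (missing cells count as failures).
    """
    errors = np.asarray(errors_pct, dtype=float)
    frames = list(frames_grid)
    order = np.argsort(frames)
    ok = np.zeros(len(frames), dtype=bool)
    col_ok = np.all(np.isfinite(errors) & (np.abs(errors) <= tolerance_pct), axis=0)
    # a column qualifies only if every column at or beyond it qualifies too
    suffix_ok = True
    for pos in reversed(order):
        suffix_ok = suffix_ok and bool(col_ok[pos])
        ok[pos] = suffix_ok
    if not ok.any():
        return None, None
    qualifying = [frames[k] for k in range(len(frames)) if ok[k]]
    cutoff = min(qualifying)
    region = errors[:, ok]
    return int(cutoff), (float(np.nanmin(region)), float(np.nanmax(region)))
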