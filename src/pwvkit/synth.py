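"""Parametric aortic flow/velocity waveforms and synthetic cohorts.

The generator stands in for patient phase-contrast curves.  One cardiac cycle
is built from a small number of physiologically named pieces, all expressed in
cycle phase ``u ∈ [0, 1)``:

* a systolic ejection pulse — raised-cosine upstroke over the first 30 % of the
  systolic window (aortic flow accelerates quickly; time-to-peak is roughly
  0.10–0.14 of the cycle) followed by a raised-cosine decline to baseline;
* an optional dicrotic wave — a small Gaussian bump just after end-systole,
  where aortic valve closure produces a secondary wave;
* an optional retrograde lobe — a negative half-sine immediately after
  systole, emulating early-diastolic backward flow (e.g. valve insufficiency);
* a flat diastolic tail at ``baseline_offset``, plus optional white noise.

Two profiles mirror the study groups: *neonate* (heart rate 138 bpm, systole
occupying 45 % of the short cycle) and *adolescent* (75 bpm, 33 %).

A synthetic subject is an ascending curve plus a descending curve that is the
same waveform circularly delayed by ``Δd / PWV`` and scaled by 0.6 (blood
diversion into the arch branches), so the ground-truth pulse wave velocity is
known by construction and every downstream estimator can be tested for
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .curves import CurvePair, SampledCurve
from .errors import ConstructionError, ParameterError

Profile = Literal["neonate", "adolescent"]

#: Diversion of blood volume into the aortic arch branches: the descending
#: curve amplitude is this fraction of the ascending one.
DESCENDING_SCALE = 0.6

# Shape constants of the waveform family (cycle-phase units).
SYSTOLE_ONSET = 0.05          # phase at which the upstroke leaves baseline
RISE_FRACTION = 0.30          # upstroke duration as a fraction of the systolic window
DICROTIC_DELAY = 0.04         # bump center after end-systole
DICROTIC_SIGMA = 0.02         # bump width (Gaussian SD)
RETROGRADE_WIDTH = 0.06       # width of the negative early-diastolic lobe


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of one synthetic aortic waveform."""

    profile: Profile = "neonate"
    heart_rate_bpm: float = 138.0
    systolic_fraction: float = 0.45
    peak_amplitude: float = 100.0
    dicrotic_amplitude_fraction: float = 0.12
    retrograde_fraction: float = 0.0
    baseline_offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.systolic_fraction < 1:
            raise ParameterError("systolic_fraction must lie in (0, 1)")
        if not self.heart_rate_bpm > 0:
            raise ParameterError("heart_rate_bpm must be positive")
        if not self.peak_amplitude > 0:
            raise ParameterError("peak_amplitude must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.dicrotic_amplitude_fraction < 0 or self.retrograde_fraction < 0:
            raise ParameterError("amplitude fractions must be non-negative")

    @property
    def cycle_duration_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm


#: Study-group defaults: Table-1 median heart rates; neonates have a relatively
#: shorter diastole, hence the larger systolic fraction.
PROFILES: dict[str, WaveformParams] = {
    "neonate": WaveformParams(profile="neonate", heart_rate_bpm=138.0,
                              systolic_fraction=0.45),
    "adolescent": WaveformParams(profile="adolescent", heart_rate_bpm=75.0,
                                 systolic_fraction=0.33),
}


def default_params(profile: Profile, **overrides) -> WaveformParams:
    """Profile defaults with optional field overrides."""
    try:
        base = PROFILES[profile]
    except KeyError:
        raise ParameterError(f"unknown profile {profile!r}") from None
    return replace(base, **overrides)


def waveform_value(params: WaveformParams, phase: np.ndarray) -> np.ndarray:
    """Noise-free waveform evaluated at arbitrary cycle phases (periodic).

    This is the continuous-time definition underlying every sampled curve; the
    cohort generator evaluates it at shifted phases so that delayed copies are
    exact, not interpolated.
    """
    u = np.asarray(phase, dtype=float) % 1.0
    A = params.peak_amplitude
    sf = params.systolic_fraction
    p0 = SYSTOLE_ONSET
    rise = RISE_FRACTION * sf
    fall = sf - rise
    y = np.zeros_like(u)

    m = (u >= p0) & (u < p0 + rise)
    y[m] = 0.5 * A * (1.0 - np.cos(np.pi * (u[m] - p0) / rise))
    m = (u >= p0 + rise) & (u < p0 + sf)
    y[m] = 0.5 * A * (1.0 + np.cos(np.pi * (u[m] - p0 - rise) / fall))

    if params.dicrotic_amplitude_fraction > 0:
        center = p0 + sf + DICROTIC_DELAY
        y += (params.dicrotic_amplitude_fraction * A
              * np.exp(-0.5 * ((u - center) / DICROTIC_SIGMA) ** 2))

    if params.retrograde_fraction > 0:
        m = (u >= p0 + sf) & (u < p0 + sf + RETROGRADE_WIDTH)
        y[m] -= (params.retrograde_fraction * A
                 * np.sin(np.pi * (u[m] - p0 - sf) / RETROGRADE_WIDTH))

    return y + params.baseline_offset


def generate_waveform(params: WaveformParams, n_frames: int,
                      kind: str = "flow", label: str = "") -> SampledCurve:
    """Sample one cardiac cycle of the parametric waveform.

    Deterministic for a fixed ``params.seed``; noise (if any) is additive
    white Gaussian with SD ``params.noise_sd``.
    """
    if n_frames < 8:
        raise ParameterError("n_frames must be at least 8")
    values = waveform_value(params, np.arange(n_frames) / n_frames)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values = values + rng.normal(0.0, params.noise_sd, n_frames)
    return SampledCurve(values=values, cycle_duration_ms=params.cycle_duration_ms,
                        kind=kind, label=label or params.profile)


@dataclass(frozen=True)
class SyntheticSubject:
    """A synthetic subject: curve pair plus its known ground-truth PWV."""

    pair: CurvePair
    true_pwv_m_per_s: float
    params: WaveformParams

    def __post_init__(self) -> None:
        if not self.true_pwv_m_per_s > 0:
            raise ParameterError("true_pwv_m_per_s must be positive")


def make_subject(params: WaveformParams, true_pwv_m_per_s: float, delta_d_mm: float,
                 n_frames: int, rng: np.random.Generator | None = None,
                 kind: str = "flow") -> SyntheticSubject:
    """Build one subject with an exactly delayed, 0.6-scaled descending curve.

    The delay is ``Δd / PWV`` (mm over m/s gives ms).  Both curves are sampled
    directly from the continuous waveform, so with zero noise the descending
    curve is an exact circular shift of the ascending one up to the amplitude
    scale.
    """
    if n_frames < 8:
        raise ParameterError("n_frames must be at least 8")
    delay_ms = delta_d_mm / true_pwv_m_per_s
    cycle_ms = params.cycle_duration_ms
    if delay_ms >= cycle_ms:
        raise ConstructionError(
            f"transit delay {delay_ms:.1f} ms is not shorter than the cardiac "
            f"cycle {cycle_ms:.1f} ms; unphysical configuration"
        )
    phase = np.arange(n_frames) / n_frames
    delay_phase = delay_ms / cycle_ms
    asc = waveform_value(params, phase)
    desc = DESCENDING_SCALE * waveform_value(params, phase - delay_phase)
    if params.noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(params.seed)
        asc = asc + rng.normal(0.0, params.noise_sd, n_frames)
        desc = desc + rng.normal(0.0, params.noise_sd, n_frames)
    pair = CurvePair(
        ascending=SampledCurve(asc, cycle_ms, kind, "ascending"),
        descending=SampledCurve(desc, cycle_ms, kind, "descending"),
        delta_d_mm=delta_d_mm,
        construction_delay_ms=delay_ms,
    )
    return SyntheticSubject(pair=pair, true_pwv_m_per_s=true_pwv_m_per_s, params=params)


def generate_cohort(n_subjects: int, profile: Profile,
                    pwv_range_m_per_s: tuple[float, float],
                    delta_d_mm: float, acquisition_frames: int,
                    noise_sd: float = 0.0, seed: int = 0,
                    kind: str = "flow") -> list[SyntheticSubject]:
    """Generate a cohort with ground-truth PWV drawn uniformly from a range.

    Each subject's true PWV is drawn reproducibly from ``pwv_range_m_per_s``
    given ``seed``; noise draws are independent per subject and per curve.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be at least 1")
    lo, hi = pwv_range_m_per_s
    if not (0 < lo <= hi <= 20):
        raise ParameterError("pwv_range must satisfy 0 < low <= high <= 20 m/s")
    if acquisition_frames < 8:
        raise ParameterError("acquisition_frames must be at least 8")
    rng = np.random.default_rng(seed)
    true_pwv = rng.uniform(lo, hi, n_subjects) if hi > lo else np.full(n_subjects, lo)
    params = default_params(profile, noise_sd=noise_sd, seed=seed)
    return [
        make_subject(params, float(pwv), delta_d_mm, acquisition_frames, rng=rng, kind=kind)
        for pwv in true_pwv
    ]
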