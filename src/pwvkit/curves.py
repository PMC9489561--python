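"""Core containers for sampled cardiac-cycle curves.

A :class:`SampledCurve` holds one cardiac cycle of flow (ml/s) or velocity
(cm/s) uniformly sampled over the cycle: sample ``k`` sits at phase
``k / n_frames`` and the cycle is treated as periodic (retrospective ECG
gating reconstructs a closed cycle).  A :class:`CurvePair` bundles the two
measurement planes — ascending aorta and a distal descending plane — with the
centerline traveling distance between them, and is the unit on which pulse
wave velocity is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import ParameterError

CurveKind = Literal["flow", "velocity"]

MIN_FRAMES = 8


@dataclass(frozen=True)
class SampledCurve:
    """One cardiac cycle of uniformly sampled flow or velocity.

    Parameters
    ----------
    values
        One sample per timeframe; flow in ml/s or velocity in cm/s.
    cycle_duration_ms
        Length of the cardiac cycle in milliseconds.
    kind
        ``"flow"`` or ``"velocity"``.
    label
        Free-text description (e.g. ``"ascending"``).
    """

    values: np.ndarray
    cycle_duration_ms: float
    kind: CurveKind = "flow"
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ParameterError("curve values must be one-dimensional")
        if vals.size < MIN_FRAMES:
            raise ParameterError(
                f"need at least {MIN_FRAMES} timeframes per cardiac cycle, got {vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise ParameterError("curve values must be finite")
        if not self.cycle_duration_ms > 0:
            raise ParameterError("cycle_duration_ms must be positive")
        if self.kind not in ("flow", "velocity"):
            raise ParameterError(f"kind must be 'flow' or 'velocity', got {self.kind!r}")

    @property
    def n_frames(self) -> int:
        """Timeframes per cardiac cycle."""
        return int(self.values.size)

    @property
    def frame_duration_ms(self) -> float:
        """Duration of one timeframe in ms (the temporal resolution)."""
        return self.cycle_duration_ms / self.n_frames

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms from cycle start."""
        return np.arange(self.n_frames) * self.frame_duration_ms

    @property
    def phases(self) -> np.ndarray:
        """Sample phases in [0, 1)."""
        return np.arange(self.n_frames) / self.n_frames

    def with_values(self, values: np.ndarray, label: str | None = None) -> "SampledCurve":
        """Copy of this curve with new sample values (same grid and metadata)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class CurvePair:
    """Ascending and descending curves plus traveling distance Δd (mm)."""

    ascending: SampledCurve
    descending: SampledCurve
    delta_d_mm: float
    # delay used during synthetic construction, if known (ms); for verification only
    construction_delay_ms: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        a, d = self.ascending, self.descending
        if a.n_frames != d.n_frames:
            raise ParameterError("ascending and descending curves must share n_frames")
        if not np.isclose(a.cycle_duration_ms, d.cycle_duration_ms):
            raise ParameterError("curves must share cycle_duration_ms")
        if a.kind != d.kind:
            raise ParameterError("curves must share kind")
        if not self.delta_d_mm > 0:
            raise ParameterError("delta_d_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.ascending.n_frames

    @property
    def cycle_duration_ms(self) -> float:
        return self.ascending.cycle_duration_ms
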