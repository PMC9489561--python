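"""Centerline traveling distance Δd.

The blood traveling distance between the two flow-measurement planes is the
arc length of the manually delineated vessel centerline, an ordered polyline
of world-space points in mm (as exported from the delineation tool; voxel
handling belongs to the segmentation software, not here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ParameterError


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D centerline points in mm."""

    points: np.ndarray          # shape (n, 3)
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ParameterError("centerline points must have shape (n, 3)")
        if pts.shape[0] < 2:
            raise ParameterError("a centerline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("centerline coordinates must be finite")
        if np.any(np.all(pts[1:] == pts[:-1], axis=1)):
            raise ParameterError("consecutive centerline points must be distinct")
        object.__setattr__(self, "points", pts)


def centerline_length(line: Centerline) -> float:
    """Arc length in mm: sum of Euclidean distances between consecutive points."""
    return float(np.linalg.norm(np.diff(line.points, axis=0), axis=1).sum())


def resample_centerline(line: Centerline, n_points: int) -> Centerline:
    """Optional smooth resampling for noisy manual point sets.

    Fits a natural cubic spline through the points parameterized by cumulative
    chord length and re-evaluates it at uniform arc positions.  Not applied by
    default anywhere: the manual polyline is used as measured.
    """
    if n_points < 2:
        raise ParameterError("n_points must be at least 2")
    pts = line.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(s, pts, axis=0, bc_type="natural")
    new = spline(np.linspace(0.0, s[-1], n_points))
    return Centerline(points=new, label=line.label)
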