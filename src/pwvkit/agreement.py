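"""Bland–Altman agreement and method summary tables.

Agreement between two measurement methods is summarized by the bias (mean of
paired differences), the SD of the differences (sample SD, n−1 denominator)
and the 95 % limits of agreement bias ± 1.96 SD.  The difference direction is
fixed as *first argument minus second* and recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

LOA_FACTOR = 1.96


@dataclass(frozen=True)
class AgreementSummary:
    """Bland–Altman bias, SD of differences and 95 % limits of agreement."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    direction: str = "a - b"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("agreement needs at least 2 pairs")


def bland_altman(a, b) -> tuple[AgreementSummary, pd.DataFrame]:
    """Agreement between paired measurements.

    Returns the summary and a per-pair table with columns ``mean`` and
    ``difference`` for plotting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("inputs must be equal-length 1D sequences")
    if a.size < 2:
        raise ParameterError("agreement needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    summary = AgreementSummary(
        bias=bias, sd=sd,
        loa_low=bias - LOA_FACTOR * sd, loa_high=bias + LOA_FACTOR * sd,
        n=int(a.size),
    )
    pairs = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    return summary, pairs


def summarize_methods(results: pd.DataFrame,
                      value_col: str = "pwv_m_per_s",
                      group_cols: tuple[str, ...] = ("method", "baseline", "kind"),
                      style: str = "mean_sd") -> pd.DataFrame:
    """Per-cell summary of a tidy results table.

    ``style="mean_sd"`` gives mean ± SD per group (method-comparison tables);
    ``style="median_range"`` gives median (min–max), the descriptive style used
    for group characteristics.  Empty groups are reported as missing, and the
    summary is invariant to input row order.
    """
    if value_col not in results.columns:
        raise ParameterError(f"missing value column {value_col!r}")
    cols = [c for c in group_cols if c in results.columns]
    if not cols:
        raise ParameterError("no grouping columns present in the results table")
    grouped = results.groupby(list(cols), dropna=False)[value_col]
    if style == "mean_sd":
        out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=0) if len(x) == 1 else x.std(ddof=1),
                          n="count")
    elif style == "median_range":
        out = grouped.agg(median="median", low="min", high="max", n="count")
    else:
        raise ParameterError(f"unknown summary style {style!r}")
    return out.reset_index()
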