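"""File dialects, manifests and the batch pipeline.

Curve CSV dialect
-----------------
First line is a metadata comment::

    # cycle_duration_ms=<float> kind=<flow|velocity> label=<text>

followed either by one value per line or by two comma-separated columns
``time_ms,value`` with a uniform time column.  The writer always emits the
two-column dialect; the reader accepts both.

Centerline CSV has a header row ``x_mm,y_mm,z_mm`` with points in traversal
order.

Every pipeline run writes a manifest (config hash, package version, timestamp)
next to its artifacts; data artifacts themselves are byte-deterministic given
the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import summarize_methods
from .curves import MIN_FRAMES, CurvePair, SampledCurve
from .errors import FormatError, ParameterError
from .geometry import Centerline
from .synth import generate_cohort
from .transit import BaselineSpec, SmoothingSpec, transit_time

_META_RE = re.compile(
    r"^#\s*cycle_duration_ms=(?P<cyc>[0-9.eE+-]+)\s+kind=(?P<kind>flow|velocity)"
    r"(?:\s+label=(?P<label>.*))?$"
)


def write_curve(curve: SampledCurve, path: str | Path) -> Path:
    """Write a curve in the two-column dialect (UTF-8, '.' decimal)."""
    path = Path(path)
    lines = [
        f"# cycle_duration_ms={float(curve.cycle_duration_ms)!r} "
        f"kind={curve.kind} label={curve.label}"
    ]
    for t, v in zip(curve.times_ms, curve.values):
        lines.append(f"{float(t)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_curve(path: str | Path) -> SampledCurve:
    """Read a curve in either dialect; validates metadata and uniform timing."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip().splitlines()
    if not text:
        raise FormatError(f"{path}: empty file")
    m = _META_RE.match(text[0].strip())
    if not m:
        raise FormatError(
            f"{path}: first line must be '# cycle_duration_ms=<float> "
            f"kind=<flow|velocity> label=<text>' (missing metadata header)"
        )
    cycle_ms = float(m.group("cyc"))
    kind = m.group("kind")
    label = (m.group("label") or "").strip()
    rows = [ln.strip() for ln in text[1:] if ln.strip() and not ln.lstrip().startswith("#")]
    if len(rows) < MIN_FRAMES:
        raise FormatError(f"{path}: {len(rows)} samples; need at least {MIN_FRAMES}")
    parsed = [[float(x) for x in ln.split(",")] for ln in rows]
    widths = {len(p) for p in parsed}
    if widths == {1}:
        values = np.array([p[0] for p in parsed])
    elif widths == {2}:
        times = np.array([p[0] for p in parsed])
        values = np.array([p[1] for p in parsed])
        step = cycle_ms / len(rows)
        expected = np.arange(len(rows)) * step
        bad = np.nonzero(~np.isclose(times, expected, rtol=1e-6, atol=1e-6))[0]
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"{path}: non-uniform time column at row {i + 2}: "
                f"got {times[i]}, expected {expected[i]}"
            )
    else:
        raise FormatError(f"{path}: rows must have 1 or 2 columns consistently")
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite values")
    return SampledCurve(values=values, cycle_duration_ms=cycle_ms, kind=kind, label=label)


def read_centerline(path: str | Path, label: str = "") -> Centerline:
    df = pd.read_csv(path)
    required = ["x_mm", "y_mm", "z_mm"]
    if not all(c in df.columns for c in required):
        raise FormatError(f"{path}: centerline CSV needs columns {required}")
    return Centerline(points=df[required].to_numpy(dtype=float), label=label)


def write_centerline(line: Centerline, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(line.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Pipeline: simulate a cohort, analyze it with every method × baseline, and
# write tidy results with a manifest.

@dataclass(frozen=True)
class RunConfig:
    """Batch-pipeline configuration (validated before any computation)."""

    out_dir: str
    n_subjects: int = 15
    profile: str = "neonate"
    pwv_min: float = 2.0
    pwv_max: float = 10.0
    delta_d_mm: float = 68.0
    acquisition_frames: int = 44
    noise_sd: float = 0.0
    seed: int = 0
    kind: str = "flow"
    methods: tuple[str, ...] = ("TTF", "max_upslope", "TTP")
    baselines: tuple[str, ...] = ("none", "automatic", "manual")
    manual_window: tuple[float, float] = (0.90, 1.0)
    sigma_cycle_fraction: float = 0.025
    write_curves: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be at least 1")
        if not (0 < self.pwv_min <= self.pwv_max <= 20):
            raise ParameterError("invalid pwv range")
        if self.acquisition_frames < MIN_FRAMES:
            raise ParameterError("acquisition_frames too small")


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir: Path, config: RunConfig, status: str,
                   error: str | None = None) -> Path:
    manifest = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "status": status,
    }
    if error is not None:
        manifest["error"] = error
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


def _baseline_spec(mode: str, manual_window: tuple[float, float]) -> BaselineSpec:
    if mode == "manual":
        return BaselineSpec(mode="manual", manual_window=manual_window)
    return BaselineSpec(mode=mode)


def analyze_pair(pair: CurvePair, methods, baselines, manual_window=(0.90, 1.0),
                 sigma_cycle_fraction: float = 0.025) -> pd.DataFrame:
    """Tidy table of transit estimates: one row per method × baseline.

    Baseline correction only applies to TTF, so other methods are evaluated
    once with baseline recorded as "none".  A zero transit time leaves the PWV
    cell missing and sets ``pwv_defined`` False.
    """
    smoothing = SmoothingSpec(sigma_cycle_fraction=sigma_cycle_fraction)
    rows = []
    for method in methods:
        modes = baselines if method == "TTF" else ("none",)
        for mode in modes:
            est = transit_time(pair, method, _baseline_spec(mode, manual_window), smoothing)
            rows.append({
                "method": method, "baseline": mode, "kind": pair.ascending.kind,
                "delta_t_ms": est.delta_t_ms,
                "landmark_asc_ms": est.landmark_asc_ms,
                "landmark_desc_ms": est.landmark_desc_ms,
                "pwv_m_per_s": est.pwv_m_per_s if est.pwv_defined else np.nan,
                "pwv_defined": est.pwv_defined,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Simulate a cohort, analyze every subject, and write artifacts.

    Outputs (under ``config.out_dir``): per-subject curve CSVs, a tidy
    ``results.csv`` (subject × method × baseline), ``summary.csv`` and
    ``manifest.json``.  Deterministic for a fixed config and seed (the
    manifest timestamp aside).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        subjects = generate_cohort(
            config.n_subjects, config.profile, (config.pwv_min, config.pwv_max),
            config.delta_d_mm, config.acquisition_frames,
            noise_sd=config.noise_sd, seed=config.seed, kind=config.kind)
        tables = []
        for i, subj in enumerate(subjects):
            sid = f"subj{i:03d}"
            if config.write_curves:
                write_curve(subj.pair.ascending, out_dir / f"{sid}_asc.csv")
                write_curve(subj.pair.descending, out_dir / f"{sid}_desc.csv")
            table = analyze_pair(subj.pair, config.methods, config.baselines,
                                 config.manual_window, config.sigma_cycle_fraction)
            table.insert(0, "subject_id", sid)
            table["true_pwv_m_per_s"] = subj.true_pwv_m_per_s
            tables.append(table)
        results = pd.concat(tables, ignore_index=True)
        results.to_csv(out_dir / "results.csv", index=False)
        summary = summarize_methods(results)
        summary.to_csv(out_dir / "summary.csv", index=False)
    except Exception as exc:
        write_manifest(out_dir, config, status="error", error=str(exc))
        raise
    write_manifest(out_dir, config, status="ok")
    return out_dir


def analyze_manifest(manifest_csv: str | Path, methods=("TTF", "max_upslope", "TTP"),
                     baselines=("none", "automatic", "manual"),
                     manual_window=(0.90, 1.0)) -> pd.DataFrame:
    """Batch analysis from a manifest CSV (subject_id, asc_path, desc_path, delta_d_mm)."""
    man = pd.read_csv(manifest_csv)
    required = ["subject_id", "asc_path", "desc_path", "delta_d_mm"]
    if not all(c in man.columns for c in required):
        raise FormatError(f"manifest needs columns {required}")
    base = Path(manifest_csv).parent
    tables = []
    for _, row in man.iterrows():
        pair = CurvePair(
            ascending=read_curve(base / str(row["asc_path"])),
            descending=read_curve(base / str(row["desc_path"])),
            delta_d_mm=float(row["delta_d_mm"]),
        )
        table = analyze_pair(pair, methods, baselines, manual_window)
        table.insert(0, "subject_id", row["subject_id"])
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
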