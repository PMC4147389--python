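"""Readers/writers for the package's delimited-text dialects, run
configuration, and report generation.

All files are comma-delimited UTF-8 with dot decimal separators and fixed
header names:

* time-activity: ``time_min,serum_cpm_per_ul[,tissue_cpm_per_g]``
* precipitation: ``compartment,time_min,raw_fraction,control_fraction``
* regional:      ``region,activity_cpm,mass_g,serum_cpm_per_ul``
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .patlak import TimeActivitySeries

__all__ = [
    "ParseError",
    "RunConfig",
    "read_time_activity",
    "write_time_activity",
    "read_precipitation",
    "read_regional",
    "report",
    "render_report",
]

TIME_ACTIVITY_COLUMNS = ("time_min", "serum_cpm_per_ul", "tissue_cpm_per_g")
PRECIPITATION_COLUMNS = ("compartment", "time_min", "raw_fraction", "control_fraction")
REGIONAL_COLUMNS = ("region", "activity_cpm", "mass_g", "serum_cpm_per_ul")


class ParseError(ValueError):
    """A malformed input file; the message names the offending row."""


@dataclass
class RunConfig:
    """Configuration for a CLI run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "."
    n_subjects: int = 6
    noise_cv: float = 0.10
    sampling_times: list[float] = field(
        default_factory=lambda: [5.0, 20.0, 30.0, 45.0, 60.0]
    )
    window_max_min: float | None = 20.0
    r2_threshold: float = 0.95
    back_extrapolate: bool = True
    arms: list[str] = field(default_factory=lambda: ["labeled_only", "with_cold"])
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _read_csv(path: str | Path, required: tuple[str, ...], optional=()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    allowed = set(required) | set(optional)
    if list(df.columns[: len(required)]) != list(required) or not set(
        df.columns
    ) <= allowed:
        raise ParseError(
            f"{path}: header must be {','.join(required)}"
            + (f"[,{','.join(optional)}]" if optional else "")
            + f"; got {','.join(df.columns)}"
        )
    return df


def read_time_activity(path: str | Path) -> TimeActivitySeries:
    """Read a time-activity CSV into a validated :class:`TimeActivitySeries`.

    Errors name the offending data row (1-based, excluding the header).
    """
    df = _read_csv(path, TIME_ACTIVITY_COLUMNS[:2], TIME_ACTIVITY_COLUMNS[2:])
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ParseError(f"{path}: row {bad[0] + 1}: non-numeric {col!r}")
        df[col] = vals
    times = df["time_min"].to_numpy(dtype=float)
    serum = df["serum_cpm_per_ul"].to_numpy(dtype=float)
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 rows, got {len(df)}")
    nonmono = np.flatnonzero(np.diff(times) <= 0)
    if nonmono.size:
        raise ParseError(
            f"{path}: row {nonmono[0] + 2}: time_min not strictly increasing"
        )
    nonpos = np.flatnonzero(serum <= 0)
    if nonpos.size:
        raise ParseError(f"{path}: row {nonpos[0] + 1}: serum_cpm_per_ul must be > 0")
    tissue = (
        df["tissue_cpm_per_g"].to_numpy(dtype=float)
        if "tissue_cpm_per_g" in df.columns
        else None
    )
    return TimeActivitySeries(times=times, serum_conc=serum, tissue_per_mass=tissue)


def write_time_activity(series: TimeActivitySeries, path: str | Path) -> None:
    """Write a series in the package dialect (round-trips with the reader)."""
    data = {"time_min": series.times, "serum_cpm_per_ul": series.serum_conc}
    if series.tissue_per_mass is not None:
        data["tissue_cpm_per_g"] = series.tissue_per_mass
    pd.DataFrame(data).to_csv(path, index=False)


def read_precipitation(path: str | Path) -> pd.DataFrame:
    """Read a precipitation-assay CSV (validated columns and ranges)."""
    df = _read_csv(path, PRECIPITATION_COLUMNS)
    bad = np.flatnonzero(
        ~df["raw_fraction"].between(0, 1) | ~df["control_fraction"].between(0, 1)
        | (df["control_fraction"] <= 0)
    )
    if bad.size:
        raise ParseError(f"{path}: row {bad[0] + 1}: fraction out of range")
    return df


def read_regional(path: str | Path) -> pd.DataFrame:
    """Read a regional-measurements CSV."""
    return _read_csv(path, REGIONAL_COLUMNS)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def render_report(results: dict) -> str:
    """Human-readable summary of a results dictionary (deterministic)."""
    if not results:
        raise ValueError("no results to report")
    lines = ["# bbbkinetics run report", ""]
    for key in sorted(results):
        lines.append(f"## {key}")
        payload = _to_jsonable(results[key])
        lines.append(json.dumps(payload, indent=2, sort_keys=True, default=str))
        lines.append("")
    return "\n".join(lines)


def report(results: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``results.json`` (machine-readable) and ``report.txt`` (human).

    ``results`` should include the run config and seed so the run can be
    reproduced; regenerating the report from the saved JSON yields identical
    content.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "results.json"
    txt_path = out / "report.txt"
    payload = _to_jsonable(results)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    txt_path.write_text(render_report(payload))
    return json_path, txt_path
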