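"""Readers, writers and configuration for the pipeline's file dialects.

All on-disk distances are micrometres; gradients alone are reported per
millimetre.  CSV dialects (units in every header's docs):

* oxygen traces — columns ``time_h, pO2_mmHg, region`` (one file may hold
  several regions);
* intensity profiles — ``day, position_um, intensity, replicate``;
* viability tables — ``region, day, replicate, live_count, dead_count``;
* proliferation tables — ``region, day, replicate, absorbance``;
* calibration tables — ``cells, absorbance``.

Geometry/config is JSON (YAML is also accepted when PyYAML is importable).
Validation errors carry 1-based data-row numbers so offending lines can be
found in the source file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import SpiralGeometry
from .migration import IntensityProfile
from .oxygen import OxygenTrace

__all__ = [
    "load_geometry",
    "read_oxygen_traces",
    "write_oxygen_traces",
    "read_profiles",
    "write_profiles",
    "read_viability",
    "read_proliferation",
    "read_calibration",
    "write_table",
]

log = logging.getLogger("spiralox")

OXYGEN_COLUMNS = ["time_h", "pO2_mmHg", "region"]
PROFILE_COLUMNS = ["day", "position_um", "intensity", "replicate"]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], name: str) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            rows = ", ".join(str(i + 1) for i in bad[:5])
            raise SchemaError(
                f"{name}: non-numeric values in column '{col}' at data row(s) {rows}"
            )
        df[col] = vals


def _require_nonnegative(df: pd.DataFrame, cols: list[str], name: str) -> None:
    for col in cols:
        bad = df.index[df[col] < 0].tolist()
        if bad:
            rows = ", ".join(str(i + 1) for i in bad[:5])
            raise SchemaError(
                f"{name}: negative values in column '{col}' at data row(s) {rows}"
            )


def load_geometry(path: str | Path) -> SpiralGeometry:
    """Load a :class:`SpiralGeometry` from a JSON (or YAML) config.

    Keys: ``D0_um, h_um, N_turns`` required; ``pitch_um, sheet_length_um,
    construct_radius_um`` optional.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml  # optional dependency, accepted when present

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    try:
        kwargs: dict[str, Any] = {
            "D0": float(cfg["D0_um"]),
            "h": float(cfg["h_um"]),
            "N": float(cfg["N_turns"]),
        }
    except KeyError as exc:
        raise SchemaError(f"{path.name}: missing geometry key {exc}") from exc
    if cfg.get("pitch_um") is not None:
        kwargs["pitch"] = float(cfg["pitch_um"])
    if cfg.get("sheet_length_um") is not None:
        kwargs["sheet_length"] = float(cfg["sheet_length_um"])
    if cfg.get("construct_radius_um") is not None:
        kwargs["construct_radius"] = float(cfg["construct_radius_um"])
    geom = SpiralGeometry(**kwargs)
    if "pitch_um" not in cfg:
        log.info("geometry: pitch defaulted to sheet thickness %g um", geom.pitch)
    if "sheet_length_um" not in cfg:
        log.info("geometry: sheet_length defaulted to %g um", geom.sheet_length)
    return geom


def read_oxygen_traces(path: str | Path) -> dict[str, OxygenTrace]:
    """Read per-region oxygen traces from one CSV file."""
    df = _read_csv(path, OXYGEN_COLUMNS)
    name = Path(path).name
    _require_numeric(df, ["time_h", "pO2_mmHg"], name)
    out: dict[str, OxygenTrace] = {}
    for region, grp in df.groupby("region", sort=True):
        grp = grp.sort_values("time_h")
        out[str(region)] = OxygenTrace(
            str(region),
            grp["time_h"].to_numpy(float),
            grp["pO2_mmHg"].to_numpy(float),
        )
    return out


def write_oxygen_traces(traces: dict[str, OxygenTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"time_h": tr.times, "pO2_mmHg": tr.pO2, "region": region}
        )
        for region, tr in sorted(traces.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[tuple[float, int, IntensityProfile]]:
    """Read intensity profiles; duplicate positions within a profile are
    merged by summing intensity (with a warning from the profile type)."""
    df = _read_csv(path, PROFILE_COLUMNS)
    name = Path(path).name
    _require_numeric(df, ["day", "position_um", "intensity", "replicate"], name)
    _require_nonnegative(df, ["intensity", "position_um"], name)
    out: list[tuple[float, int, IntensityProfile]] = []
    for (day, rep), grp in df.groupby(["day", "replicate"], sort=True):
        grp = grp.sort_values("position_um")
        out.append(
            (
                float(day),
                int(rep),
                IntensityProfile(
                    float(day),
                    grp["position_um"].to_numpy(float),
                    grp["intensity"].to_numpy(float),
                ),
            )
        )
    return out


def write_profiles(
    profiles: list[tuple[float, int, IntensityProfile]], path: str | Path
) -> None:
    frames = [
        pd.DataFrame(
            {
                "day": day,
                "position_um": prof.positions,
                "intensity": prof.intensities,
                "replicate": rep,
            }
        )
        for day, rep, prof in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_viability(path: str | Path) -> pd.DataFrame:
    from .population import VIABILITY_COLUMNS

    df = _read_csv(path, VIABILITY_COLUMNS)
    name = Path(path).name
    _require_numeric(df, ["day", "replicate", "live_count", "dead_count"], name)
    _require_nonnegative(df, ["live_count", "dead_count"], name)
    zero = df.index[(df["live_count"] + df["dead_count"]) <= 0].tolist()
    if zero:
        rows = ", ".join(str(i + 1) for i in zero[:5])
        raise SchemaError(f"{name}: live + dead is zero at data row(s) {rows}")
    return df


def read_proliferation(path: str | Path) -> pd.DataFrame:
    from .population import PROLIFERATION_COLUMNS

    df = _read_csv(path, PROLIFERATION_COLUMNS)
    _require_numeric(df, ["day", "replicate", "absorbance"], Path(path).name)
    return df


def read_calibration(path: str | Path) -> pd.DataFrame:
    from .population import CALIBRATION_COLUMNS

    df = _read_csv(path, CALIBRATION_COLUMNS)
    name = Path(path).name
    _require_numeric(df, ["cells", "absorbance"], name)
    _require_nonnegative(df, ["cells"], name)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_json(obj: Any, path: str | Path) -> None:
    """Write a JSON report with deterministic key ordering."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
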