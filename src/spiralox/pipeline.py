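"""Run configuration and the consolidated end-of-run report.

``RunConfig`` names the inputs (geometry config plus any of the stage CSVs)
and the analysis parameters; ``run_report`` executes every stage whose
input is present and joins the results into a single JSON-serialisable
report with deterministic field ordering.  Every defaulted parameter is
logged at INFO so inferred constants (1.75 mm radial path, sheet-length
spiral path) are always visible in provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import io as sio
from .errors import SchemaError
from .geometry import SpiralGeometry, segment_boundaries, total_spiral_length
from .migration import cohort_speed, cohort_stats
from .oxygen import (
    DEFAULT_RADIAL_PATH_MM,
    plateau_detect,
    percent_change,
    radial_gradient,
    spiral_gradient,
    value_at,
)
from .population import fit_standard_curve, proliferation_percent, viability_summary

__all__ = ["RunConfig", "run_report"]

log = logging.getLogger("spiralox")


@dataclass
class RunConfig:
    """Inputs and parameters for one consolidated analysis run."""

    geometry: SpiralGeometry
    profiles_path: str | None = None
    oxygen_path: str | None = None
    viability_path: str | None = None
    proliferation_path: str | None = None
    calibration_path: str | None = None
    quantile: float = 0.5
    plateau_window: float = 1.0  # h
    slope_tol: float = 2.0  # mmHg/h
    radial_path_mm: float = DEFAULT_RADIAL_PATH_MM
    spiral_path_mm: float | None = None  # defaults to sheet_length
    with_period: bool = True
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        if "geometry" not in cfg:
            raise SchemaError(f"{Path(path).name}: missing 'geometry' object")
        g = cfg["geometry"]
        geom = SpiralGeometry(
            D0=float(g["D0_um"]),
            h=float(g["h_um"]),
            N=float(g["N_turns"]),
            **{
                k: float(g[j])
                for k, j in [
                    ("pitch", "pitch_um"),
                    ("sheet_length", "sheet_length_um"),
                    ("construct_radius", "construct_radius_um"),
                ]
                if g.get(j) is not None
            },
        )
        base = Path(path).parent
        paths = cfg.get("paths", {})

        def _resolve(key: str) -> str | None:
            v = paths.get(key)
            if v is None:
                return None
            p = Path(v)
            return str(p if p.is_absolute() else base / p)

        params = cfg.get("parameters", {})
        return cls(
            geometry=geom,
            profiles_path=_resolve("profiles"),
            oxygen_path=_resolve("oxygen"),
            viability_path=_resolve("viability"),
            proliferation_path=_resolve("proliferation"),
            calibration_path=_resolve("calibration"),
            quantile=float(params.get("quantile", 0.5)),
            plateau_window=float(params.get("plateau_window_h", 1.0)),
            slope_tol=float(params.get("slope_tol_mmHg_per_h", 2.0)),
            radial_path_mm=float(
                params.get("radial_path_mm", DEFAULT_RADIAL_PATH_MM)
            ),
            spiral_path_mm=(
                float(params["spiral_path_mm"])
                if params.get("spiral_path_mm") is not None
                else None
            ),
            with_period=bool(params.get("with_period", True)),
            seed=int(cfg.get("seed", 0)),
        )


def _geometry_section(geom: SpiralGeometry) -> dict[str, Any]:
    b = segment_boundaries(geom)
    return {
        "total_spiral_length_um": total_spiral_length(geom),
        "sheet_length_um": geom.sheet_length,
        "core_middle_boundary_s_um": b.s_core_middle,
        "middle_outer_boundary_s_um": b.s_middle_outer,
        "core_middle_boundary_r_um": b.r_core_middle,
        "middle_outer_boundary_r_um": b.r_middle_outer,
    }


def _oxygen_section(run: RunConfig) -> dict[str, Any]:
    traces = sio.read_oxygen_traces(run.oxygen_path)
    spiral_path = run.spiral_path_mm
    if spiral_path is None:
        spiral_path = run.geometry.sheet_length / 1000.0
        log.info("oxygen: spiral path defaulted to sheet length %.3g mm", spiral_path)
    section: dict[str, Any] = {"plateaus": {}, "percent_change": {}}
    finals: dict[str, float] = {}
    for region, trace in sorted(traces.items()):
        res = plateau_detect(trace, run.plateau_window, run.slope_tol)
        final = value_at(trace, float(trace.times[-1]))
        finals[region] = final
        section["plateaus"][region] = {
            "time_h": res.time,
            "pO2_mmHg": res.value,
            "plateau_found": res.plateau_found,
        }
        section["percent_change"][region] = percent_change(res.value, final)
    if "outer" in finals and "core" in finals:
        g_r = radial_gradient(finals["outer"], finals["core"], run.radial_path_mm)
        g_s = spiral_gradient(
            g_r, run.geometry, run.radial_path_mm, spiral_path
        )
        section["radial_gradient_mmHg_per_mm"] = g_r.gradient
        section["spiral_gradient_mmHg_per_mm"] = g_s.gradient
        section["delta_p_mmHg"] = g_r.delta_p
        section["radial_path_mm"] = run.radial_path_mm
        section["spiral_path_mm"] = spiral_path
    return section


def _migration_section(run: RunConfig) -> dict[str, Any]:
    profiles = sio.read_profiles(run.profiles_path)
    per_day: dict[float, dict[str, list[float]]] = {}
    for day, _rep, prof in profiles:
        st = cohort_stats(prof, run.geometry, run.quantile, run.with_period)
        d = per_day.setdefault(day, {"radial": [], "spiral": [], "iqr": [], "period": []})
        d["radial"].append(st.median_radial)
        d["spiral"].append(st.median_spiral)
        d["iqr"].append(st.iqr_radial)
        if st.period_um is not None:
            d["period"].append(st.period_um)

    def _mean_se(vals: list[float]) -> dict[str, float]:
        arr = np.asarray(vals, float)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return {"mean": float(arr.mean()), "se": se, "n": int(arr.size)}

    days = sorted(per_day)
    stats = {
        f"{day:g}": {
            "median_radial_um": _mean_se(per_day[day]["radial"]),
            "median_spiral_um": _mean_se(per_day[day]["spiral"]),
            "iqr_radial_um": _mean_se(per_day[day]["iqr"]),
            **(
                {"period_um": _mean_se(per_day[day]["period"])}
                if per_day[day]["period"]
                else {}
            ),
        }
        for day in days
    }
    speeds = {}
    for a, b in zip(days[:-1], days[1:]):
        speeds[f"day{a:g}_to_day{b:g}"] = {
            "radial_um_per_day": cohort_speed(
                stats[f"{a:g}"]["median_radial_um"]["mean"], a,
                stats[f"{b:g}"]["median_radial_um"]["mean"], b,
            ),
            "spiral_um_per_day": cohort_speed(
                stats[f"{a:g}"]["median_spiral_um"]["mean"], a,
                stats[f"{b:g}"]["median_spiral_um"]["mean"], b,
            ),
        }
    return {"per_day": stats, "speeds": speeds}


def _population_section(run: RunConfig) -> dict[str, Any]:
    section: dict[str, Any] = {}
    if run.viability_path is not None:
        _, summary = viability_summary(sio.read_viability(run.viability_path))
        section["viability"] = [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in row.items()}
            for row in summary.to_dict("records")
        ]
    if run.proliferation_path is not None:
        if run.calibration_path is None:
            raise SchemaError(
                "stage 'population/proliferation' requires a calibration table"
            )
        curve = fit_standard_curve(sio.read_calibration(run.calibration_path))
        _, summary = proliferation_percent(
            sio.read_proliferation(run.proliferation_path), curve
        )
        section["standard_curve"] = {
            "slope_cells_per_unit": curve.slope,
            "intercept_cells": curve.intercept,
            "residual_se_cells": curve.residual_se,
        }
        section["proliferation"] = [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in row.items()}
            for row in summary.to_dict("records")
        ]
    return section


def run_report(run: RunConfig) -> dict[str, Any]:
    """Execute every configured stage and join the results.

    Raises :class:`FileNotFoundError` naming the stage whose input is
    missing on disk.
    """
    report: dict[str, Any] = {
        "geometry": _geometry_section(run.geometry),
        "parameters": {
            "quantile": run.quantile,
            "plateau_window_h": run.plateau_window,
            "slope_tol_mmHg_per_h": run.slope_tol,
            "radial_path_mm": run.radial_path_mm,
            "seed": run.seed,
        },
    }
    for name, path in [
        ("oxygen", run.oxygen_path),
        ("migration", run.profiles_path),
        ("viability", run.viability_path),
        ("proliferation", run.proliferation_path),
    ]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"stage '{name}': input not found: {path}")
    if run.oxygen_path is not None:
        report["oxygen"] = _oxygen_section(run)
    if run.profiles_path is not None:
        report["migration"] = _migration_section(run)
    pop = _population_section(run)
    if pop:
        report["population"] = pop
    return report
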