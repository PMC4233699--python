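"""Oxygen probe time-series analysis.

Fibre-optic probes log oxygen partial pressure (mmHg) in the outer, middle
and core regions of a spiralled construct.  Cellular metabolism depletes the
core rapidly — pO2 falls to a quasi-steady plateau within about an hour —
and a slow partial recovery follows as the cell distribution rebalances.
This module extracts plateau values, percent recoveries, and the oxygen
partial-pressure gradient expressed per millimetre of either radial or
spiral path.  The same pressure difference spread over the much longer
spiral path gives a far shallower spiral gradient, which is the quantity a
cell migrating inside a collagen layer actually experiences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "OxygenTrace",
    "GradientResult",
    "PlateauResult",
    "value_at",
    "plateau_detect",
    "percent_change",
    "radial_gradient",
    "spiral_gradient",
]

#: Default radial probe separation, mm: the construct radius (3.5 mm diameter).
DEFAULT_RADIAL_PATH_MM = 1.75
#: Default spiral core-to-outer path, mm: the unrolled sheet length.
DEFAULT_SPIRAL_PATH_MM = 60.0

RegionName = Literal["core", "middle", "outer", "ambient"]


@dataclass(frozen=True)
class OxygenTrace:
    """Oxygen partial-pressure time series for one probe location.

    ``times`` in hours (strictly increasing, >= 2 samples), ``pO2`` in mmHg
    (within [0, 200] — 7.6 mmHg corresponds to 1% oxygen, ambient medium
    sits near 140 mmHg).
    """

    region: RegionName
    times: np.ndarray
    pO2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pO2, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pO2", p)
        if t.ndim != 1 or p.ndim != 1 or t.size != p.size:
            raise ValidationError("times and pO2 must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValidationError("an oxygen trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(p < 0) or np.any(p > 200):
            raise ValidationError("pO2 values must lie in [0, 200] mmHg")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class GradientResult:
    """An oxygen gradient: pressure difference over a path length."""

    delta_p: float  # mmHg
    path_length: float  # mm
    gradient: float  # mmHg / mm
    coordinate: Literal["radial", "spiral"]


@dataclass(frozen=True)
class PlateauResult:
    """First quasi-steady window of a depletion trace."""

    time: float  # h, start of the compliant window
    value: float  # mmHg, mean pO2 over the window
    plateau_found: bool


def value_at(trace: OxygenTrace, t: float) -> float:
    """Linearly interpolated pO2 (mmHg) at time ``t`` (h); no extrapolation."""
    if t < trace.times[0] or t > trace.times[-1]:
        raise DomainError(
            f"t={t:g} h outside the trace span "
            f"[{trace.times[0]:g}, {trace.times[-1]:g}] h"
        )
    return float(np.interp(t, trace.times, trace.pO2))


def plateau_detect(
    trace: OxygenTrace, window: float = 1.0, slope_tol: float = 2.0
) -> PlateauResult:
    """Locate the first quasi-steady plateau of a depletion trace.

    Scans windows ``[t*, t* + window]`` (h) anchored at each sample and
    returns the earliest one whose least-squares slope has magnitude at most
    ``slope_tol`` (mmHg/h), together with the mean pO2 over that window.  If
    no window qualifies, returns the global-minimum sample flagged
    ``plateau_found=False``.

    Defaults (1 h window, 2 mmHg/h) reflect the first-hour depletion phase
    of seeded constructs.
    """
    t, p = trace.times, trace.pO2
    if trace.span < window:
        raise DomainError(
            f"trace spans {trace.span:g} h, shorter than the {window:g} h window"
        )
    any_window = False
    for i in range(t.size):
        j = int(np.searchsorted(t, t[i] + window, side="right"))
        if j - i < 3 or t[j - 1] - t[i] < window * 0.5:
            continue
        any_window = True
        tw, pw = t[i:j], p[i:j]
        slope = np.polyfit(tw, pw, 1)[0]
        if abs(slope) <= slope_tol:
            return PlateauResult(float(t[i]), float(pw.mean()), True)
    if not any_window:
        raise ValidationError(
            "trace too sparse: no window contains at least 3 samples"
        )
    k = int(np.argmin(p))
    return PlateauResult(float(t[k]), float(p[k]), False)


def percent_change(p_from: float, p_to: float) -> float:
    """Percent change from ``p_from`` to ``p_to`` (both mmHg, p_from > 0)."""
    if p_from <= 0:
        raise DomainError(f"reference pressure must be > 0, got {p_from:g}")
    return 100.0 * (p_to - p_from) / p_from


def radial_gradient(
    p_outer: float, p_inner: float, radial_path: float = DEFAULT_RADIAL_PATH_MM
) -> GradientResult:
    """Radial oxygen gradient between the outer and inner probes, mmHg/mm."""
    if radial_path <= 0:
        raise DomainError(f"radial path must be > 0 mm, got {radial_path:g}")
    dp = p_outer - p_inner
    return GradientResult(dp, radial_path, dp / radial_path, "radial")


def spiral_gradient(
    radial: GradientResult,
    geom=None,
    radial_path: float = DEFAULT_RADIAL_PATH_MM,
    spiral_path: float | None = None,
) -> GradientResult:
    """Re-express a radial gradient per millimetre of spiral path.

    The same pressure difference acts over both paths, so
    ``g_spiral = g_radial * radial_path / spiral_path``.  When a
    :class:`~spiralox.geometry.SpiralGeometry` is supplied the spiral path
    defaults to its sheet length; otherwise 60 mm.  Radial path defaults to
    the 1.75 mm construct radius.
    """
    if spiral_path is None:
        spiral_path = (
            geom.sheet_length / 1000.0 if geom is not None else DEFAULT_SPIRAL_PATH_MM
        )
    if radial_path <= 0 or spiral_path <= 0:
        raise DomainError(
            f"paths must be > 0 mm, got radial={radial_path:g}, "
            f"spiral={spiral_path:g}"
        )
    g = radial.gradient * radial_path / spiral_path
    dp = radial.gradient * radial_path
    return GradientResult(dp, spiral_path, g, "spiral")


def trace_from_samples(
    region: RegionName, times: Sequence[float], pO2: Sequence[float]
) -> OxygenTrace:
    """Convenience constructor from plain sequences."""
    return OxygenTrace(region, np.asarray(times, float), np.asarray(pO2, float))
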