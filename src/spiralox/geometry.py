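"""Rolled-sheet spiral coordinate model.

A plastic-compressed collagen sheet rolled into a tight multi-turn cylinder
admits two natural coordinates for a point in the sheet: the radial distance
``r`` outward from the construct axis, and the spiral (arc-length) distance
``s`` measured from the construct origin along the sheet's centreline.  With
inner diameter ``D0``, radial advance per turn ``pitch`` and ``n`` (possibly
fractional) turns completed, the centreline arc length is

    s(n) = pi * n * (D0 + pitch * (n - 1))

which at integer ``n = N`` is the classical rolled-sheet length
``L = pi N (D0 + h (N - 1))`` when the pitch equals the sheet thickness
``h``.  The map ``r -> s`` is a monotone quadratic and is inverted exactly.

The unrolled sheet is cut into three equal-length segments — core (innermost),
middle and outer — so segment boundaries live at thirds of the sheet length
measured along the centreline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "SpiralGeometry",
    "SegmentBoundaries",
    "total_spiral_length",
    "radial_to_spiral",
    "spiral_to_radial",
    "arc_jacobian",
    "segment_boundaries",
    "region_of",
]

Region = Literal["core", "middle", "outer"]

#: Default unrolled sheet length, um: three 20-mm segments.
DEFAULT_SHEET_LENGTH_UM = 60_000.0


@dataclass(frozen=True)
class SpiralGeometry:
    """Parameters of a rolled collagen sheet.

    Parameters
    ----------
    D0 : float
        Inner diameter of the spiral, um.
    h : float
        Collagen sheet thickness, um.
    N : float
        Number of turns (>= 1).
    pitch : float, optional
        Effective radial advance per turn, um.  Defaults to ``h`` (a tight
        spiral with layers in contact); larger values represent fluid gaps
        between layers.
    sheet_length : float, optional
        Total unrolled sheet length along the centreline, um.  Defaults to
        60 000 um (three 20-mm segments).  Kept independent of the turn
        formula so that segment boundaries follow the cutting protocol even
        when the two disagree.
    construct_radius : float, optional
        Outer radius of the physical construct, um.  Defaults to the tight
        spiral outer radius ``D0/2 + pitch * N``.
    """

    D0: float
    h: float
    N: float
    pitch: float | None = None
    sheet_length: float = DEFAULT_SHEET_LENGTH_UM
    construct_radius: float | None = None

    def __post_init__(self) -> None:
        if self.pitch is None:
            object.__setattr__(self, "pitch", float(self.h))
        if self.construct_radius is None:
            object.__setattr__(
                self, "construct_radius", self.D0 / 2.0 + self.pitch * self.N
            )
        if not self.D0 > 0:
            raise ValidationError(f"inner diameter D0 must be > 0, got {self.D0}")
        if not self.h > 0:
            raise ValidationError(f"sheet thickness h must be > 0, got {self.h}")
        if not self.N >= 1:
            raise ValidationError(f"number of turns N must be >= 1, got {self.N}")
        if not self.pitch >= self.h:
            raise ValidationError(
                f"pitch ({self.pitch}) must be >= sheet thickness h ({self.h})"
            )
        if not self.sheet_length > 0:
            raise ValidationError(
                f"sheet_length must be > 0, got {self.sheet_length}"
            )
        if not self.construct_radius >= self.D0 / 2.0:
            raise ValidationError(
                f"construct_radius ({self.construct_radius}) must be >= D0/2"
            )

    @property
    def inner_radius(self) -> float:
        """Radius at the construct origin, um (``D0`` is a diameter)."""
        return self.D0 / 2.0

    @property
    def outer_spiral_radius(self) -> float:
        """Radial extent of the spiral's ``N`` turns, um."""
        return self.D0 / 2.0 + self.pitch * self.N


def total_spiral_length(geom: SpiralGeometry) -> float:
    """Centreline length of the full ``N``-turn spiral, um.

    Evaluates ``pi * N * (D0 + pitch * (N - 1))``, algebraically identical to
    the sum of per-turn circumferences ``sum_k pi * (D0 + 2 * pitch * k)``.
    """
    return math.pi * geom.N * (geom.D0 + geom.pitch * (geom.N - 1.0))


def _turns_from_radius(geom: SpiralGeometry, r):
    return (np.asarray(r, dtype=float) - geom.D0 / 2.0) / geom.pitch


def _arc_from_turns(geom: SpiralGeometry, n):
    return np.pi * n * (geom.D0 + geom.pitch * (n - 1.0))


def radial_to_spiral(geom: SpiralGeometry, r):
    """Map radial distance ``r`` (um) to centreline arc length ``s`` (um).

    Uses the continuous fractional-turn extension
    ``s = pi * n * (D0 + pitch * (n - 1))`` with ``n = (r - D0/2) / pitch``.
    Accepts scalars or arrays; strictly increasing in ``r`` whenever
    ``pitch <= D0`` (for wider pitches the extension dips below zero inside
    the first partial turn, where the mean-circumference model breaks
    down).

    Raises
    ------
    DomainError
        If ``r`` lies outside ``[D0/2, D0/2 + pitch * N]``.
    """
    r_arr = np.asarray(r, dtype=float)
    lo, hi = geom.inner_radius, geom.outer_spiral_radius
    tol = 1e-9 * max(hi, 1.0)
    if np.any(r_arr < lo - tol) or np.any(r_arr > hi + tol):
        raise DomainError(
            f"radial distance must lie in [{lo:g}, {hi:g}] um, got "
            f"values in [{r_arr.min():g}, {r_arr.max():g}]"
        )
    n = np.clip(_turns_from_radius(geom, r_arr), 0.0, geom.N)
    s = _arc_from_turns(geom, n)
    return float(s) if np.isscalar(r) or np.ndim(r) == 0 else s


def _spiral_to_radial_unchecked(geom: SpiralGeometry, s):
    """Invert the arc-length quadratic without the upper-domain clamp.

    ``s(n)`` is quadratic in ``n``; the non-negative root is

        n = (-(D0 - pitch) + sqrt((D0 - pitch)^2 + 4 * pitch * s / pi))
            / (2 * pitch)

    Valid for any ``s >= 0``, including arc lengths beyond the ``N``-turn
    formula length (needed when the physical sheet is longer than the tight
    spiral arithmetic implies).
    """
    s_arr = np.asarray(s, dtype=float)
    b = geom.D0 - geom.pitch
    disc = b * b + 4.0 * geom.pitch * s_arr / np.pi
    n = (-b + np.sqrt(disc)) / (2.0 * geom.pitch)
    return geom.D0 / 2.0 + geom.pitch * n


def spiral_to_radial(geom: SpiralGeometry, s):
    """Map centreline arc length ``s`` (um) back to radial distance (um).

    Exact inverse of :func:`radial_to_spiral`; the round trip reproduces the
    input to 1e-9 relative tolerance.

    Raises
    ------
    DomainError
        If ``s`` lies outside ``[0, total_spiral_length(geom)]``.
    """
    s_arr = np.asarray(s, dtype=float)
    L = total_spiral_length(geom)
    tol = 1e-9 * max(L, 1.0)
    if np.any(s_arr < -tol) or np.any(s_arr > L + tol):
        raise DomainError(
            f"spiral distance must lie in [0, {L:g}] um, got values in "
            f"[{s_arr.min():g}, {s_arr.max():g}]"
        )
    r = _spiral_to_radial_unchecked(geom, np.clip(s_arr, 0.0, L))
    return float(r) if np.isscalar(s) or np.ndim(s) == 0 else r


def arc_jacobian(geom: SpiralGeometry, r):
    """Derivative ds/dr at radius ``r``, dimensionless.

    ``ds/dr = pi * (2 r - pitch) / pitch`` — roughly one circumference per
    pitch, so outer turns accumulate arc length much faster than inner ones.
    """
    r_arr = np.asarray(r, dtype=float)
    j = np.pi * (2.0 * r_arr - geom.pitch) / geom.pitch
    return float(j) if np.isscalar(r) or np.ndim(r) == 0 else j


@dataclass(frozen=True)
class SegmentBoundaries:
    """Core/middle and middle/outer boundaries in both coordinates, um."""

    s_core_middle: float
    s_middle_outer: float
    r_core_middle: float
    r_middle_outer: float


def segment_boundaries(geom: SpiralGeometry) -> SegmentBoundaries:
    """Boundaries of the three equal sheet segments.

    The unrolled sheet is cut into thirds along the centreline, core
    innermost, so the boundaries sit at ``sheet_length / 3`` and
    ``2 * sheet_length / 3`` spiral distance from the construct origin.
    Radial images use the continuous quadratic inversion, which remains
    defined when the sheet is longer than the ``N``-turn formula length.
    """
    s1 = geom.sheet_length / 3.0
    s2 = 2.0 * geom.sheet_length / 3.0
    r1 = float(_spiral_to_radial_unchecked(geom, s1))
    r2 = float(_spiral_to_radial_unchecked(geom, s2))
    return SegmentBoundaries(s1, s2, r1, r2)


def region_of(geom: SpiralGeometry, s: float) -> Region:
    """Assign a spiral position to core/middle/outer.

    Half-open intervals ``[0, L/3)``, ``[L/3, 2L/3)``, ``[2L/3, L]`` with
    ``L = sheet_length``, so every admissible ``s`` belongs to exactly one
    region.
    """
    L = geom.sheet_length
    if s < 0 or s > L:
        raise DomainError(f"spiral position must lie in [0, {L:g}] um, got {s:g}")
    if s < L / 3.0:
        return "core"
    if s < 2.0 * L / 3.0:
        return "middle"
    return "outer"
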