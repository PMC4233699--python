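"""Synthetic fixture generators with known ground truth.

The study's raw probe traces, line profiles and replicate tables are not
deposited, so every analysis stage is exercised against generated inputs
whose true parameters are known:

* two-phase oxygen traces — fast first-hour exponential depletion to a
  plateau followed by a slow exponential recovery (a phenomenological form;
  no mechanistic diffusion-consumption model is implied);
* migrating-cohort intensity profiles — a Gaussian cohort in the spiral
  coordinate, drifting at a constant speed after an onset day, multiplied by
  a periodic layer-occupancy comb and mapped to the radial axis through the
  spiral geometry (including the arc-length Jacobian);
* region x day viability/proliferation tables drawn around supplied target
  percentages, plus a linear calibration table.

All generators are bit-reproducible given (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import (
    SpiralGeometry,
    arc_jacobian,
    radial_to_spiral,
    spiral_to_radial,
    total_spiral_length,
)
from .migration import IntensityProfile
from .oxygen import OxygenTrace

__all__ = [
    "RegionOxygenParams",
    "OxygenScenario",
    "CohortScenario",
    "CohortTruth",
    "PopulationTables",
    "default_oxygen_scenario",
    "default_population_targets",
    "gen_oxygen_trace",
    "gen_cohort_profiles",
    "gen_population_tables",
    "spiral_sd_for_radial_spread",
]


@dataclass(frozen=True)
class RegionOxygenParams:
    """Two-exponential trace parameters for one probe region.

    ``p(t) = plateau_p + (ambient_p - plateau_p) * exp(-t / decay_tau)
           + recovery_amp * (1 - exp(-t / recovery_tau))``
    """

    ambient_p: float  # mmHg, t = 0 value
    plateau_p: float  # mmHg, post-depletion quasi-steady level
    decay_tau: float  # h, depletion time constant
    recovery_amp: float  # mmHg, asymptotic recovery above the plateau
    recovery_tau: float  # h, recovery time constant

    def __post_init__(self) -> None:
        if self.decay_tau <= 0 or self.recovery_tau <= 0:
            raise ValidationError("time constants must be positive")
        if self.plateau_p > self.ambient_p:
            raise ValidationError("plateau_p must not exceed ambient_p")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.plateau_p
            + (self.ambient_p - self.plateau_p) * np.exp(-t / self.decay_tau)
            + self.recovery_amp * (1.0 - np.exp(-t / self.recovery_tau))
        )


@dataclass(frozen=True)
class OxygenScenario:
    """Per-region oxygen trace parameters plus measurement noise."""

    regions: dict[str, RegionOxygenParams]
    noise_sd: float = 0.0  # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def default_oxygen_scenario(noise_sd: float = 1.0, seed: int = 0) -> OxygenScenario:
    """Scenario with the study's headline trace shape.

    Ambient medium at 140 mmHg; first-hour depletion to plateaus near 22.3
    (core), 28.9 (middle) and 100.0 mmHg (outer); 140-h values near 43.2,
    49.1 and 100.0 mmHg.  The monotone two-exponential form cannot
    represent the middle/outer local maxima near 100 h, so amplitudes and
    time constants are set to land on the 140-h endpoint values instead.
    """
    regions = {
        "core": RegionOxygenParams(140.0, 22.0, 0.25, 23.5, 60.0),
        "middle": RegionOxygenParams(140.0, 28.9, 0.25, 22.4, 60.0),
        "outer": RegionOxygenParams(140.0, 100.0, 0.30, 0.0, 40.0),
    }
    return OxygenScenario(regions, noise_sd=noise_sd, seed=seed)


def gen_oxygen_trace(
    scn: OxygenScenario, times: np.ndarray
) -> dict[str, OxygenTrace]:
    """Generate one :class:`OxygenTrace` per scenario region.

    Gaussian noise is seeded and applied independently per region;
    pressures are clipped to the physical [0, 200] mmHg range.
    """
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(scn.seed)
    out: dict[str, OxygenTrace] = {}
    for region in sorted(scn.regions):
        p = scn.regions[region].evaluate(t)
        if scn.noise_sd > 0:
            p = p + rng.normal(0.0, scn.noise_sd, size=t.size)
        out[region] = OxygenTrace(region, t, np.clip(p, 0.0, 200.0))
    return out


@dataclass(frozen=True)
class CohortScenario:
    """A Gaussian cohort drifting along the spiral inside collagen layers.

    The cohort density is Gaussian in the spiral coordinate with median
    ``s0 + speed * max(0, day - onset_day)`` and spread ``sd_s`` (um); the
    delayed onset emulates a population that holds position for the first
    days of culture and then chemotaxes at constant speed.  Layer occupancy
    multiplies the mapped radial density by a comb of period ``geom.pitch``
    and duty cycle ``duty`` (fraction of each pitch occupied by collagen).
    """

    geom: SpiralGeometry
    s0: float  # um, initial cohort median (spiral coordinate)
    sd_s: float  # um, cohort spread (spiral coordinate)
    speed: float  # um/day after onset
    onset_day: float = 5.0
    duty: float = 0.5
    sample_spacing: float = 5.0  # um, radial sampling step
    noise_sd: float = 0.0  # intensity units (profiles peak near 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty <= 1.0:
            raise ValidationError("duty must lie in (0, 1]")
        if self.sd_s <= 0:
            raise ValidationError("sd_s must be positive")
        if self.sample_spacing <= 0:
            raise ValidationError("sample_spacing must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def median_at(self, day: float) -> float:
        return self.s0 + self.speed * max(0.0, day - self.onset_day)


@dataclass(frozen=True)
class CohortTruth:
    """Generator ground truth for parameter-recovery tests.

    ``median_spiral``/``median_radial`` are the Gaussian-envelope medians;
    ``profile_median_radial``/``profile_median_spiral`` are the medians of
    the noiseless comb-modulated density the generator actually produced
    (computed by quadrature on a 10x finer grid).  The two differ by up to
    about half a layer period because the comb locks mass to collagen
    bands.
    """

    median_spiral: dict[float, float]
    median_radial: dict[float, float]
    profile_median_radial: dict[float, float]
    profile_median_spiral: dict[float, float]
    speed: float
    onset_day: float
    period_um: float | None


def spiral_sd_for_radial_spread(
    geom: SpiralGeometry, r_center: float, sd_r: float
) -> float:
    """Spiral-coordinate sd giving radial spread ``sd_r`` near ``r_center``.

    The arc-length Jacobian ds/dr compresses spiral-coordinate widths into
    narrow radial bands, so a cohort spanning several collagen layers
    radially corresponds to a spiral sd larger by that factor.
    """
    return sd_r * float(arc_jacobian(geom, r_center))


def gen_cohort_profiles(
    scn: CohortScenario, days: list[float], replicates: int = 3
) -> tuple[list[tuple[float, int, IntensityProfile]], CohortTruth]:
    """Generate radial intensity profiles for each day and replicate.

    The radial density is ``f_s(s(r)) * ds/dr * comb(r)`` — the Jacobian
    keeps total intensity conserved across days as the cohort drifts.  All
    days share one normalisation constant (the global noiseless peak), so
    conservation is observable; seeded Gaussian noise is added per
    replicate and clipped at zero.  Raises if any day's median +/- 2 sd
    leaves the spiral span (tails beyond it are truncated).
    """
    geom = scn.geom
    L = total_spiral_length(geom)
    for day in days:
        mu = scn.median_at(day)
        if mu - 2.0 * scn.sd_s < 0.0 or mu + 2.0 * scn.sd_s > L:
            raise ValidationError(
                f"cohort at day {day:g} (median {mu:g} um, sd {scn.sd_s:g} um) "
                f"extends beyond the spiral span [0, {L:g}] um"
            )
    r = np.arange(
        geom.inner_radius,
        geom.outer_spiral_radius + scn.sample_spacing / 2.0,
        scn.sample_spacing,
    )
    s = np.asarray(radial_to_spiral(geom, r))
    jac = np.asarray(arc_jacobian(geom, r))
    layer_phase = np.mod(r - geom.inner_radius, geom.pitch) / geom.pitch
    comb = (layer_phase < scn.duty).astype(float)

    clean: dict[float, np.ndarray] = {}
    for day in days:
        mu = scn.median_at(day)
        dens = np.exp(-0.5 * ((s - mu) / scn.sd_s) ** 2) * jac * comb
        clean[day] = dens
    peak = max(float(d.max()) for d in clean.values())
    if peak <= 0:
        raise ValidationError("generated profiles are identically zero")

    rng = np.random.default_rng(scn.seed)
    profiles: list[tuple[float, int, IntensityProfile]] = []
    for day in days:
        base = clean[day] / peak
        for rep in range(replicates):
            y = base.copy()
            if scn.noise_sd > 0:
                y = np.clip(y + rng.normal(0.0, scn.noise_sd, size=y.size), 0.0, None)
            profiles.append((day, rep, IntensityProfile(day, r.copy(), y)))

    med_s = {day: scn.median_at(day) for day in days}
    med_r = {day: float(spiral_to_radial(geom, m)) for day, m in med_s.items()}

    # discrete truth: median of the noiseless comb density, fine-grid quadrature
    rf = np.arange(
        geom.inner_radius,
        geom.outer_spiral_radius,
        scn.sample_spacing / 10.0,
    )
    sf = np.asarray(radial_to_spiral(geom, rf))
    jf = np.asarray(arc_jacobian(geom, rf))
    combf = (np.mod(rf - geom.inner_radius, geom.pitch) / geom.pitch < scn.duty)
    prof_med_r: dict[float, float] = {}
    for day in days:
        mu = scn.median_at(day)
        df = np.exp(-0.5 * ((sf - mu) / scn.sd_s) ** 2) * jf * combf
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (df[1:] + df[:-1]) * np.diff(rf))])
        prof_med_r[day] = float(np.interp(0.5 * cum[-1], cum, rf))
    prof_med_s = {
        day: float(radial_to_spiral(geom, r)) for day, r in prof_med_r.items()
    }
    truth = CohortTruth(
        med_s,
        med_r,
        prof_med_r,
        prof_med_s,
        scn.speed,
        scn.onset_day,
        geom.pitch if scn.duty < 1.0 else None,
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# population tables


@dataclass(frozen=True)
class PopulationTables:
    """Generated viability/proliferation/calibration tables plus truth."""

    viability: pd.DataFrame
    proliferation: pd.DataFrame
    calibration: pd.DataFrame
    viability_targets: dict[tuple[str, int], float]
    proliferation_targets: dict[tuple[str, int], float]
    cal_slope: float
    cal_intercept: float


def default_population_targets() -> tuple[
    dict[tuple[str, int], float], dict[tuple[str, int], float]
]:
    """Region x day target percentages emulating the study's summaries.

    Viability endpoints follow the reported trajectories (outer rising from
    78.8% to 84.3% at day 5 then 82.6% at day 10; middle 80.1 -> 76.4%;
    core 78.6 -> 71.6%); unreported intermediate days are linearly
    interpolated.  Proliferation (percent of day-1 outer baseline) uses the
    reported outer values (128.0 at day 5, 136.1 at day 7, 134.7 at day 10)
    with middle/core reconstructed from the reported outer-minus-region
    differences.
    """
    viability = {
        ("outer", 1): 78.8, ("outer", 3): 81.0, ("outer", 5): 84.3,
        ("outer", 7): 83.4, ("outer", 10): 82.6,
        ("middle", 1): 80.1, ("middle", 3): 79.3, ("middle", 5): 78.5,
        ("middle", 7): 77.4, ("middle", 10): 76.4,
        ("core", 1): 78.6, ("core", 3): 77.0, ("core", 5): 75.5,
        ("core", 7): 73.5, ("core", 10): 71.6,
    }
    proliferation = {
        ("outer", 1): 100.0, ("outer", 3): 114.0, ("outer", 5): 128.0,
        ("outer", 7): 136.1, ("outer", 10): 134.7,
        ("middle", 1): 100.0, ("middle", 3): 104.4, ("middle", 5): 88.3,
        ("middle", 7): 106.8, ("middle", 10): 107.6,
        ("core", 1): 100.0, ("core", 3): 91.2, ("core", 5): 84.9,
        ("core", 7): 94.2, ("core", 10): 100.5,
    }
    return viability, proliferation


def gen_population_tables(
    viability_targets: dict[tuple[str, int], float] | None = None,
    proliferation_targets: dict[tuple[str, int], float] | None = None,
    noise_sd: float = 2.0,
    replicates: int = 3,
    seed: int = 0,
    total_count: int = 1000,
    baseline_cells: float = 1.0e6,
    cal_slope: float = 1.0e6,
    cal_intercept: float = 0.0,
    cal_noise_sd: float = 0.0,
) -> PopulationTables:
    """Draw replicate tables around target percentages.

    Noise is additive in percentage points (``noise_sd``), so the expected
    per-cell summary equals the target; viability rows are realised as
    live/dead counts out of ``total_count`` cells per replicate pool, and
    proliferation rows as absorbances on an exactly linear calibration
    (``cells = cal_slope * A + cal_intercept``) with optional seeded noise
    on the calibration readings.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if viability_targets is None or proliferation_targets is None:
        dv, dp = default_population_targets()
        viability_targets = viability_targets or dv
        proliferation_targets = proliferation_targets or dp
    rng = np.random.default_rng(seed)

    via_rows = []
    for (region, day), target in sorted(viability_targets.items()):
        for rep in range(replicates):
            v = target + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            v = float(np.clip(v, 0.0, 100.0))
            live = int(round(total_count * v / 100.0))
            via_rows.append(
                {"region": region, "day": day, "replicate": rep,
                 "live_count": live, "dead_count": total_count - live}
            )
    viability = pd.DataFrame(via_rows)

    pro_rows = []
    for (region, day), target in sorted(proliferation_targets.items()):
        for rep in range(replicates):
            pct = target + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            cells = baseline_cells * pct / 100.0
            absorbance = (cells - cal_intercept) / cal_slope
            pro_rows.append(
                {"region": region, "day": day, "replicate": rep,
                 "absorbance": absorbance}
            )
    proliferation = pd.DataFrame(pro_rows)

    cal_cells = np.linspace(0.0, 2.0 * baseline_cells, 9)
    cal_abs = (cal_cells - cal_intercept) / cal_slope
    if cal_noise_sd > 0:
        cal_abs = cal_abs + rng.normal(0.0, cal_noise_sd, size=cal_abs.size)
    calibration = pd.DataFrame({"cells": cal_cells, "absorbance": cal_abs})

    return PopulationTables(
        viability, proliferation, calibration,
        dict(viability_targets), dict(proliferation_targets),
        cal_slope, cal_intercept,
    )
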