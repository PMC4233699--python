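"""Cohort migration statistics from intensity profiles.

Generates layer-modulated profiles of a labelled cohort that holds its
position for five days and then chemotaxes along the spiral at
1015 um/day, then recovers medians, spread, layer periodicity and speed
with the analysis pipeline.
"""

import numpy as np

from spiralox import (
    CohortScenario,
    SpiralGeometry,
    cohort_speed,
    cohort_stats,
    gen_cohort_profiles,
    radial_to_spiral,
    spiral_sd_for_radial_spread,
)

geom = SpiralGeometry(D0=80.0, h=80.0, N=40)
r_mid = (geom.inner_radius + geom.outer_spiral_radius) / 2.0
scn = CohortScenario(
    geom=geom,
    s0=float(radial_to_spiral(geom, r_mid)),
    sd_s=spiral_sd_for_radial_spread(geom, r_mid, 300.0),
    speed=1015.0,
    onset_day=5.0,
    duty=0.5,
    sample_spacing=5.0,
    noise_sd=0.05,
    seed=0,
)
profiles, truth = gen_cohort_profiles(scn, [0.0, 5.0, 10.0], replicates=3)

medians: dict[float, list] = {}
for day, _rep, prof in profiles:
    st = cohort_stats(prof, geom)
    medians.setdefault(day, []).append(st)

for day in sorted(medians):
    sts = medians[day]
    mr = np.mean([s.median_radial for s in sts])
    ms = np.mean([s.median_spiral for s in sts])
    iqr = np.mean([s.iqr_radial for s in sts])
    per = np.mean([s.period_um for s in sts if s.period_um])
    print(
        f"day {day:4.0f}: median {mr:7.1f} um radial / {ms:8.0f} um spiral, "
        f"IQR {iqr:5.0f} um, layer period {per:5.1f} um"
    )

m = {d: float(np.mean([s.median_spiral for s in v])) for d, v in medians.items()}
print(f"spiral speed day 0-5:  {cohort_speed(m[0.0], 0, m[5.0], 5):7.1f} um/day")
print(f"spiral speed day 5-10: {cohort_speed(m[5.0], 5, m[10.0], 10):7.1f} um/day")
print(f"generator truth after onset:   {truth.speed:7.1f} um/day")
# The pre-onset speed is ~0 and the post-onset estimate recovers the true
# drift within one radial-bin-equivalent per day (5 um radial ~ 630 um
# spiral at this radius).  The layer comb quantises the median to collagen
# bands, so a drift of about half a layer period carries the largest such
# error; the ~80 um period marks the layers the cells migrate within.
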