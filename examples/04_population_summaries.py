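"""Viability and proliferation summaries per region and day.

Generates replicate live/dead tables and Alamar-blue absorbances around
study-like targets, fits the linear standard curve, and prints the mean
+/- SE summaries the figure-level plots show.
"""

from spiralox import (
    fit_standard_curve,
    gen_population_tables,
    proliferation_percent,
    relative_difference,
    viability_summary,
)

tables = gen_population_tables(noise_sd=2.0, replicates=3, seed=0)

_, via = viability_summary(tables.viability)
print("viability (% live, mean +/- SE):")
for _, row in via.sort_values(["region", "day"]).iterrows():
    print(f"  {row.region:>6} day {row.day:2.0f}: {row['mean']:5.1f} +/- {row['sem']:4.2f}")

curve = fit_standard_curve(tables.calibration)
print(f"standard curve: {curve.slope:.3g} cells per absorbance unit")

_, pro = proliferation_percent(tables.proliferation, curve)
print("proliferation (% of day-1 outer baseline):")
for _, row in pro.sort_values(["region", "day"]).iterrows():
    print(f"  {row.region:>6} day {row.day:2.0f}: {row['mean']:6.1f} +/- {row['sem']:4.2f}")

outer10 = via[(via.region == "outer") & (via.day == 10)]["mean"].iloc[0]
core10 = via[(via.region == "core") & (via.day == 10)]["mean"].iloc[0]
print(
    f"day-10 core viability is {relative_difference(outer10, core10):.1f}% "
    f"lower than the outer region"
)
# High-oxygen outer regions proliferate fastest and stay most viable; the
# hypoxic core loses viability over the ten-day culture.
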