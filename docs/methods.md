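# Methods

`spiralox` quantifies the interplay between diffusion-limited oxygen
gradients and cell fate (proliferation, viability, chemotaxis) in spiralled
plastic-compressed collagen constructs: a dense, cell-laden collagen sheet
(~80 μm thick) rolled into a multi-turn cylinder and cultured in medium, so
oxygen reaches embedded cells only by diffusion from the outer surface.

## The spiral coordinate model

A point in the rolled sheet has two natural coordinates: the radial
distance *r* from the construct axis and the arc length *s* from the
construct origin along the sheet centreline.  With inner diameter *D₀*,
radial advance per turn (pitch) *p* and *n* fractional turns,

  s(n) = π n (D₀ + p (n − 1)),  n = (r − D₀/2) / p.

At integer *n = N* this is the classical rolled-sheet length
L = π N (D₀ + h (N − 1)) when the pitch equals the sheet thickness *h*, and
it is algebraically identical to the sum of per-turn circumferences
Σₖ π (D₀ + 2 p k).  The map is a monotone quadratic in *n* (for p ≤ D₀) and
is inverted exactly by taking the non-negative root; the round trip is
exact to 1e−9 relative tolerance.  For p > D₀ the continuous extension is
not monotone inside the first partial turn (the mean-circumference model
breaks down there); the study geometry (D₀ = p = 80 μm) is the boundary
case and is handled exactly.

Design choices made where the construction was genuinely open:

* **Pitch vs thickness.**  Alternate layers of the rolled sheet are not in
  contact (fluid gaps), yet the length formula uses the sheet thickness.
  We expose `pitch` as an independent parameter defaulting to `h`, so the
  classical formula is the default and gapped geometries remain
  representable.
* **Sheet length is decoupled from the turn formula.**  The construct is
  cut into three equal 20-mm segments (core, middle, outer), i.e. a 60-mm
  sheet, but the N = 9 formula length is ≈20.4 mm — the two printed facts
  are mutually inconsistent.  Segment boundaries therefore live at thirds
  of the configurable `sheet_length` (default 60 000 μm), and their radial
  images use the quadratic inversion without the N-turn upper clamp.
  Region assignment uses half-open thirds [0, L/3), [L/3, 2L/3), [2L/3, L],
  core innermost, so every position belongs to exactly one region.
* The reported core/middle boundary pair (1006 μm radial, 19 869 μm
  spiral) cannot be reproduced from D₀ = 80 μm, h = 80 μm, N = 9 under any
  mapping we derived (it implies an effective pitch near 140 μm); it is
  recorded as a known discrepancy, not hard-coded.

## Oxygen trace analysis

Probe traces (pO₂ in mmHg vs hours; ambient medium ≈140 mmHg, 7.6 mmHg per
1% O₂) are interpolated linearly with no smoothing.  Plateau detection
scans windows [t*, t* + w] (default w = 1 h, matching the first-hour
depletion phase) and returns the earliest window whose least-squares slope
magnitude is ≤ 2 mmHg/h (configurable), with the window-mean pO₂; traces
with no compliant window return the global minimum flagged
`plateau_found=False`.  The plateau value is therefore within
`slope_tol × window` of a monotone trace's asymptote.

Gradients divide a pressure difference by a path length in mm.  The radial
path defaults to the 1.75 mm construct radius (3.5 mm diameter); probe
positions are not otherwise specified, and this default reproduces the
reported 20-h radial gradient to within rounding.  The spiral gradient
re-expresses the same Δp per millimetre of spiral path (default: the 60 mm
sheet length), so g_radial / g_spiral = d_spiral / d_radial identically.

## Migration statistics

Stain intensity along a radial line profile is taken as proportional to
cell density.  The trapezoidal cumulative intensity, normalised to end at
1, is the probability a cell resides within a given distance of the origin;
the 50% residence distance (median) is the primary cohort position (the
intensity-weighted mean is also reported), the interquartile range measures
spread, and the displacement of the median between days gives the migration
speed.  Quantiles are computed radially and converted to the spiral
coordinate afterwards; for a monotone map the order of conversion and
quantile-taking commutes, and a test asserts this.  Duplicate positions are
merged by summing intensity; an optional constant-background subtraction
(explicit value, or the 25th intensity percentile) handles line-profile
exports with a baseline offset.

Layer periodicity: profiles are resampled to a uniform grid, detrended by
a moving average (window 3× the expected ~80 μm pitch), and the lag of the
first significant positive autocorrelation peak past the first zero
crossing (parabolically refined) is the period.  Autocorrelation is used
rather than a raw Fourier peak because it is robust to the cohort envelope;
the resolution is limited by the sample spacing, and profiles spanning
fewer than three periods, or with no positive peak, return "no period".

## Population summaries

A linear standard curve (ordinary least squares, `scipy.stats.linregress`)
converts resazurin absorbance to cell number (floored at zero).  The two
raw wavelength readings (510/590 nm) must be combined upstream — no
reduction formula is published, so the pipeline accepts one pre-combined
absorbance column rather than inventing one.  Proliferation is cell number
as a percent of the day-1 outer-region baseline (the mean over day-1 outer
replicates, so the baseline itself is exactly 100%).  Viability is
100·live/(live+dead).  Both are aggregated as mean ± standard error over
replicates (three per condition by default); ANOVA-style significance
testing is deliberately left to standard statistics packages, which can
consume the per-replicate tables directly.

## Synthetic data generators

The study deposited no raw data, so generators with known ground truth
stand in:

* **Oxygen**: p(t) = plateau + (ambient − plateau)·e^(−t/τ_d) +
  A·(1 − e^(−t/τ_r)) + seeded Gaussian noise.  This monotone two-exponential
  form is phenomenological; defaults land on ambient 140 mmHg, plateaus
  22.0/28.9/100.0 mmHg and 140-h values 43.2/49.1/100.0 mmHg
  (core/middle/outer).  It cannot represent the non-monotone late decline
  seen in middle/outer traces around 100 h; no computed quantity depends
  on that feature.
* **Cohort profiles**: the cohort is Gaussian in the *spiral* coordinate
  (cells migrate along the sheet within layers), with median
  s₀ + v·max(0, day − onset) — stationary until onset day 5, then constant
  drift at v (default 1015 μm/day).  The radial profile is
  f_s(s(r))·(ds/dr)·comb(r): the arc-length Jacobian conserves total
  intensity as the cohort drifts, and the comb (period = pitch, duty 0.5
  ≈ 80 μm collagen in a 160 μm effective pitch-like band structure) models
  layer occupancy.  Because ds/dr ≈ 2πr/p is large (30–130 across the
  span), a cohort spanning several layers radially corresponds to a spiral
  sd of tens of thousands of μm; the helper `spiral_sd_for_radial_spread`
  converts a radial spread (default 300 μm, matching profiles that span
  several layers) into the equivalent spiral sd.  A 40-turn geometry is
  used for cohort fixtures so a multi-layer cohort fits within ±2σ of the
  span; generation fails if it does not, and tails beyond the span are
  truncated.  The generator records both the envelope medians and the
  medians of the noiseless comb-modulated density it actually produced
  (by quadrature on a 10× finer grid): the comb locks mass to collagen
  bands, so the two differ by up to about half a layer period, and median
  recovery is asserted against the discrete truth while speed recovery is
  asserted against the envelope speed with a one-bin-per-day tolerance.
  Noise is Gaussian on the unit-peak profile (default SNR 10–20), clipped
  at zero.
* **Population tables**: replicate viability and proliferation values are
  drawn with additive percentage-point noise around region × day targets
  (so expected summaries equal the targets), realised as live/dead counts
  out of 1000 cells and as absorbances on an exactly linear calibration
  (10⁶ cells per absorbance unit, zero intercept by default).  Default
  targets follow the reported trajectories, with unreported intermediate
  days linearly interpolated and middle/core proliferation reconstructed
  from the reported outer-minus-region differences.

All generators are bit-reproducible given (scenario, seed); every source of
randomness flows from a single `numpy` `default_rng(seed)`.

What the generators do **not** emulate: mechanistic oxygen
diffusion–consumption kinetics, cell division/death dynamics (tables are
drawn around targets, not evolved), image segmentation artefacts, the
non-monotone late oxygen decline, and regions where alternate collagen
layers touch ("short-circuit" migration paths).  Passing recovery tests
therefore demonstrates correctness of the coordinate arithmetic and the
statistical pipeline under the assumed data structure, not the biological
model itself.

## Numerical choices and problem sizes

Radial profiles are sampled at 5 μm (641 points across a 40-turn span);
oxygen traces at 15-min intervals over 140 h; replicate counts default to
3.  Property suites use 100 random geometries, 1000-point round-trip
grids, and up to 1000 replicates for law-of-large-numbers checks; the full
test suite runs in a few seconds on one CPU.  Percent/gradient arithmetic
on reported summary values is reproduced within ±1% relative tolerance,
reflecting the source's rounding of intermediates.

## Known limitations

* The reported radial migration speed of 392 μm/day is inconsistent with
  the reported radial medians (355 → 620 μm over 5 days = 53 μm/day); the
  pipeline reproduces the positions and the spiral speed and flags the
  radial speed rather than targeting it.
* The coordinate map's continuous extension is not monotone for
  pitch > D₀ (first partial turn only).
* Period estimation needs ≥3 periods of span and breaks down below
  SNR ≈ 2; the comb quantises cohort medians to collagen bands (error up
  to ~half a period, largest when the drift is near half a period).
* The 3.5 mm stated construct diameter exceeds the N = 9 tight-spiral outer
  diameter (≈1.52 mm); fluid gaps presumably account for the difference,
  but no gap value is published, so the construct radius and spiral-path
  defaults are independent parameters rather than derived quantities.
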