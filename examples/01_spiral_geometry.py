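"""Spiral coordinate model of a rolled collagen sheet.

Builds the construct geometry (80 um inner diameter, 80 um sheet, 9 turns),
prints the centreline length, maps a radial position to its spiral distance
and back, and shows the core/middle/outer segment boundaries.
"""

from spiralox import (
    SpiralGeometry,
    radial_to_spiral,
    segment_boundaries,
    spiral_to_radial,
    total_spiral_length,
)

geom = SpiralGeometry(D0=80.0, h=80.0, N=9)
L = total_spiral_length(geom)
print(f"total spiral length L = {L:.0f} um  (pi * 9 * (80 + 80*8) = 6480*pi)")

r = 400.0
s = radial_to_spiral(geom, r)
print(f"a cell {r:.0f} um from the axis sits {s:.0f} um along the spiral")
print(f"round trip: s -> r gives {spiral_to_radial(geom, s):.1f} um")

b = segment_boundaries(geom)
print(
    f"segment boundaries (thirds of the {geom.sheet_length/1000:.0f} mm sheet): "
    f"core/middle at s = {b.s_core_middle:.0f} um, "
    f"middle/outer at s = {b.s_middle_outer:.0f} um"
)
# The spiral coordinate grows quadratically with radius: a short radial step
# in the outer turns corresponds to a much longer path along the sheet.
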