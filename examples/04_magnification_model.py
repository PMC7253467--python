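"""Areal/volume magnification consequences of a measured retardation.

Takes one measured cell — severe-arrest OPL at 300 µm control eccentricity,
retardation 199 µm with thickness ratio 1.14 — and derives what it implies
for the space available to cone pedicles.
"""

import foveametry as fm

E, R, T = 300.0, 199.0, 1.14

A = fm.area_ratio(E, R)
V = fm.volume_ratio(T, A)
d = fm.pedicle_diameter(A)
sphere = fm.sphere_equivalent_diameter_ratio(A)

print(f"control eccentricity E = {E:.0f} µm, retardation R = {R:.0f} µm")
print(f"area ratio   ((E-R)/E)^2      = {A:.4f}  (prints {fm.round_half_up(A,2):.2f})")
print(f"volume ratio T x A            = {V:.4f}  (prints {fm.round_half_up(V,2):.2f})")
print(f"pedicle diameter 6.3*sqrt(A)  = {d:.2f} µm (prints {fm.round_half_up(d,1)} µm)")
print(f"sphere-equivalent diameter    = {100*sphere:.1f}% of control "
      f"(prints {fm.round_half_up(100*sphere):.0f}%)")
print("\nReading: mass that should occupy a ring at 300 µm is still within "
      "101 µm of the centre, so the available lateral area shrinks to ~11% "
      "and a 6.3 µm cone pedicle must fit into a 2.1 µm footprint.")
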