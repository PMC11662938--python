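"""Alpha-solenoid geometry: superhelical parameters, hinges, FRET pairs.

Builds ideal extended (apo: rise 8.5 A, twist 36 deg) and compact (bound:
rise 4.8 A, twist 40 deg) solenoid models of a 18-repeat protein, re-fits
their superhelical parameters, decomposes the conformational change into
per-junction screw rotations, and screens residue pairs 8 repeats apart for
FRET contrast across the 54-A Forster radius of a Cy3/AF647 pair.
"""

import numpy as np

from pprfret import (
    SolenoidSpec,
    fit_superhelix,
    generate_ideal_solenoid,
    inter_repeat_transforms,
    predict_fret_from_distance,
    screen_fret_pairs,
)

apo = generate_ideal_solenoid(SolenoidSpec(rise=8.5, twist=36.0, radius=25.0, n_repeats=18))
bound = generate_ideal_solenoid(SolenoidSpec(rise=4.8, twist=40.0, radius=25.0, n_repeats=18))

for name, cs in (("apo", apo), ("bound", bound)):
    p = fit_superhelix(cs)
    print(f"{name:6s}: rise {p.rise:.2f} A  twist {p.twist:.1f} deg  "
          f"radius {p.radius:.1f} A  pitch {p.pitch:.1f} A  "
          f"repeats/turn {p.repeats_per_turn:.1f}")
print("  (compaction nearly halves the pitch and overwinds the superhelix)")

tfs = inter_repeat_transforms(apo, bound)
angles = [t.rotation_angle for t in tfs]
print(f"inter-repeat screw rotations apo->bound: {np.mean(angles):.1f} deg mean "
      f"(max superposition RMSD {max(t.rmsd for t in tfs):.2e} A)")
print("  (each repeat moves as a rigid body; a small per-junction hinge")
print("   rotation accumulates into the global compaction)")

hits = screen_fret_pairs(apo, bound, r0=54.0, separation=8)
top = hits[0]
print(f"FRET-pair screen (separation 8 repeats, R0 = 54 A): {len(hits)} candidates")
print(f"best pair: residues {top.residue_1}/{top.residue_2}, "
      f"r_apo {top.r_apo:.0f} A -> r_bound {top.r_bound:.0f} A, "
      f"E {top.e_apo:.2f} -> {top.e_bound:.2f}")
print(f"sanity: E(r = R0) = {predict_fret_from_distance(54.0, 54.0):.2f}")
print("  (pairs straddling the Forster radius give the largest efficiency")
print("   change, which is what makes the compaction detectable by smFRET)")
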