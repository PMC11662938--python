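"""Fit a dissociation constant from an ensemble FRET titration.

A 5 nM FRET sensor is titrated with a 12-point ligand series from 1000 nM
down to 0.01 nM. Because the sensor concentration exceeds the Kd, free and
total ligand differ appreciably (ligand depletion) and the fit uses the
quadratic mass-balance isotherm rather than a simple hyperbola.
"""

import numpy as np

from pprfret import TitrationModel, fit_kd, simulate_titration

model = TitrationModel(kd=1.2, sensor_conc=5.0, noise_sd=0.02)
curve = simulate_titration(model, seed=42)

fit = fit_kd(curve)
print("ligand (nM)   observed FRET   fitted FRET")
for L, y, p in zip(curve.ligand_concs, curve.observed_fret,
                   fit.predict(curve.ligand_concs, 5.0)):
    print(f"{L:10.2f}   {y:10.3f}      {p:7.3f}")
print()
print(f"fitted Kd (this curve) = {fit.kd:.2f} +/- {fit.kd_se:.2f} nM "
      f"(generation value 1.2 nM)")
print(f"FRET endpoints: free {fit.fret_free:.3f}, bound {fit.fret_bound:.3f}")
print(f"identifiable: {fit.identifiable}, near-stoichiometric: {fit.near_stoichiometric}")

# a single 12-point curve at 2% noise determines Kd only to ~50%;
# replicates tighten it
kds = [fit_kd(simulate_titration(model, seed=s)).kd for s in range(20)]
print(f"20 replicate curves: median Kd {np.median(kds):.2f} nM "
      f"(IQR {np.percentile(kds, 25):.2f}-{np.percentile(kds, 75):.2f})")
print()
print("The depletion isotherm is essential here: with a 5 nM sensor and a")
print("~1 nM Kd, half the added ligand is bound near the transition, so a")
print("hyperbolic (free = total) fit would overestimate the constant.")
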