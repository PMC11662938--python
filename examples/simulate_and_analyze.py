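"""Simulate a two-state smFRET cohort and recover its states end to end.

Builds 25 traces of a surface-immobilized FRET sensor switching between an
unbound (E = 0.4) and an RNA-bound (E = 0.8) conformation at 0.1/s each way,
with donor->acceptor crosstalk g = 0.07, FRET-equivalent noise of 0.08 and
photobleaching. Crosstalk is calibrated on 10 donor-only molecules, each
trace is truncated at its first detected bleach, denoised with the NL
forward-backward filter and idealized with the variational HMM.
"""

import numpy as np

from pprfret import (
    AnalysisConfig,
    HMMPriors,
    NLFilterParams,
    estimate_crosstalk,
    simulate_donor_only_cohort,
    simulate_two_state_cohort,
)
from pprfret.kinetics import collate_histogram, residence_times
from pprfret.pipeline import analyze_traces
from pprfret.protocols import study_photophysics
from pprfret.simulate import two_state_scheme

phys = study_photophysics()  # I=1000, g=0.07, sigma_E=0.08, lifetime 120 s
scheme = two_state_scheme(fret_unbound=0.4, fret_bound=0.8, k_on=0.1, k_off=0.1)

traces = simulate_two_state_cohort(25, scheme, phys, seed=7, duration=120.0)
donor_only = simulate_donor_only_cohort(10, phys, seed=8, duration=120.0)

g = estimate_crosstalk(donor_only)
print(f"calibrated crosstalk g = {g.g:.4f}  (generation value 0.07)")

trajs, denoised, fits = analyze_traces(
    traces, g, NLFilterParams(), HMMPriors(), AnalysisConfig(), seed=1
)
print(f"molecules analyzed: {len(fits)} / {len(traces)}")

ideal = np.concatenate([f.idealized for f in fits])
lo, hi = ideal[ideal < 0.5], ideal[ideal >= 0.5]
print(f"recovered state means: unbound {lo.mean():.3f}, bound {hi.mean():.3f}")
print("  (generation values 0.400 / 0.800; the HMM separates the two")
print("   conformations despite per-frame noise comparable to their gap)")

dwells = [d for f in fits for d in residence_times(f, cfg=AnalysisConfig())]
hi_dwell = [d.duration for d in dwells if d.cls == "T_high-low"]
lo_dwell = [d.duration for d in dwells if d.cls == "T_low-high"]
print(f"dwells kept after censoring rules: {len(dwells)}")
print(f"mean bound dwell {np.mean(hi_dwell):.2f} s, unbound {np.mean(lo_dwell):.2f} s")
print("  (exchange at 0.1/s gives ~10 s true dwells; the minimum-residence")
print("   rule discards sub-0.4 s events and the terminal dwell is deleted)")

hist = collate_histogram(trajs)
peak = hist.loc[hist["count"].idxmax(), "bin_center"]
print(f"pooled FRET histogram: mode at E = {peak:.2f}, integral of density = "
      f"{(hist['density'] * np.diff(hist['bin_center'].iloc[:2]).item()).sum():.6f}")
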