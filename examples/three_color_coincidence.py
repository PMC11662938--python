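"""Three-color ALEX: does RNA arrival coincide with sensor compaction?

A labeled RNA (blue dye, 488-nm excitation) binds an immobilized two-color
FRET sensor (532-nm excitation) under alternating lasers. If binding and
conformational compaction are simultaneous, every T_low-high transition of
the sensor FRET should align with the onset of 488-excited fluorescence to
within one frame - the best the alternation scheme can resolve.
"""

import numpy as np

from pprfret import CrosstalkModel, InjectionConfig, fit_hmm, simulate_injection_cohort
from pprfret.fretcalc import locate_bleach
from pprfret.protocols import study_photophysics
from pprfret.threecolor import correlate_binding, demultiplex_alex

phys = study_photophysics(fret_sd=0.05)
inj = InjectionConfig(injection_time=5.0, wait_mean=12.0, fraction_stable=1.0)
traces = simulate_injection_cohort(
    25, inj, phys, seed=21, duration=120.0, three_color=True
)

lags = []
low488, high488 = [], []
for tr in traces:
    call = locate_bleach(tr)  # truncate at the first dye bleach, as always
    if call.dark or call.acceptor_dead:
        continue
    if call.truncation_frame is not None:
        if call.truncation_frame < 20:
            continue
        tr = tr.slice(call.truncation_frame)
    alex = demultiplex_alex(tr, CrosstalkModel(0.07))
    if len(alex.fret_ppr.fret) < 20:
        continue
    fit = fit_hmm(alex.fret_ppr, seed=0)
    if fit.k < 2:
        continue
    summ = correlate_binding(fit, alex)
    lags.extend(summ.lags_frames.tolist())
    low488.extend(summ.total488_low.tolist())
    high488.extend(summ.total488_high.tolist())

lags = np.array(lags)
print(f"binding events with a detected 488 onset: {len(lags)}")
print(f"lag distribution (original frames): "
      f"median {np.median(lags):.0f}, max |lag| {np.max(np.abs(lags)):.0f}")
print("  (532 and 488 frames interleave, so |lag| <= 1 frame means the RNA")
print("   signal and the FRET transition are simultaneous at frame precision)")
print(f"total 488 fluorescence, sensor unbound: {np.median(low488):8.0f} (median)")
print(f"total 488 fluorescence, sensor bound:   {np.median(high488):8.0f} (median)")
print("  (signal appears only while the sensor sits in its high-FRET,")
print("   RNA-bound conformation - direct binding, no scanning intermediate)")
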