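"""Time-to-first-binding from a simulated solution-injection experiment.

Ligand is injected at t = 10 s into a flow cell of 60 immobilized sensor
molecules; each binds after an exponential wait of mean 10.6 s. The pipeline
must recover that wait from the FRET trajectories alone, with photobleaching
censoring the slowest binders.
"""

import numpy as np

from pprfret.protocols import injection_experiment

summary = injection_experiment(seed=3, n=60, wait_mean=10.6)

print(f"molecules analyzed: {summary['n']}, binding observed in {summary['n_observed']}, "
      f"censored by photobleach: {summary['n_censored']}")
print(f"mean time to first binding (observed events): "
      f"{summary['mean']:.1f} +/- {summary['sem']:.1f} s")
print(f"censoring-corrected (exposure MLE) estimate:  "
      f"{summary['rate_corrected_mean']:.1f} s")
print(f"generation wait mean: {summary['generation_wait_mean']} s")
gt = summary["ground_truth_waits"]
print(f"ground-truth waits drawn this run: mean {np.mean(gt):.1f} s, n {len(gt)}")
print()
print("Photobleaching preferentially censors long waits, so the mean over")
print("observed events underestimates the true wait; the exposure-time")
print("estimator divides total unbound observation time by the number of")
print("binding events and is consistent for exponential waits.")
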