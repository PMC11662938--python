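# pprfret

Single-molecule FRET analysis of designer pentatricopeptide-repeat (dPPR)
RNA sensors — for biophysicists who study sequence-specific RNA binding
with surface-immobilized FRET sensors, and for anyone who needs a tested,
scriptable version of the standard smFRET trace-analysis chain.

A dPPR protein is an α-solenoid whose ~35-residue repeats each read one
ssRNA base. Binding compacts the solenoid (rise 8.5 → 4.8 Å per repeat,
twist 36° → 40°, pitch = rise·360/twist nearly halved), moving a
donor/acceptor pair placed 8 repeats apart across the Förster radius
(R0 = 54 Å) and switching the sensor from E ≈ 0.4 to E ≈ 0.8. The package
covers both sides of such an experiment:

**Trace analysis** — per-frame efficiency with crosstalk correction,

    E = CI_A / (CI_A + I_D),   CI_A = I_A − g·I_D,

g calibrated on donor-only molecules; photobleach step detection
(penalized change-point fit) with trajectory truncation and molecule QC;
nonlinear forward–backward (NL) denoising; state finding by a variational
Bayes HMM (Gaussian emissions, Normal–Gamma emission priors, evidence-based
selection of the state count); dwell-time kinetics with the standard
censoring rules (terminal dwell deleted, dwells < 2·F·N_FA discarded),
binding/release rates, dynamic fractions, time-to-first-binding with
censoring-corrected estimation, synchronized transition averages, and
three-color ALEX coincidence analysis.

**Structure and ensemble assays** — ideal α-solenoid models and
superhelical parameter fitting (radius, rise, twist, pitch), inter-repeat
rigid-body/hinge screw decomposition, residue-pair distance series,
Förster-based FRET-pair screening (E = 1/(1+(r/R0)⁶)), and dissociation
constants from ensemble titrations via the 1:1 ligand-depletion isotherm.

A first-class synthetic-data generator simulates two- and three-color
trace cohorts with exact continuous-time kinetics, crosstalk,
photobleaching and noise, so every stage of the analysis is validated by
parameter recovery against known ground truth. See `docs/methods.md` for
models, assumptions and numerical choices.

## Worked example

`examples/simulate_and_analyze.py` simulates 25 switching sensor traces
plus 10 donor-only calibration molecules and runs the full chain:

```
calibrated crosstalk g = 0.0723  (generation value 0.07)
molecules analyzed: 25 / 25
recovered state means: unbound 0.399, bound 0.802
dwells kept after censoring rules: 177
mean bound dwell 10.38 s, unbound 9.99 s
pooled FRET histogram: mode at E = 0.41, integral of density = 1.000000
```

The calibration recovers the generation crosstalk, the HMM separates the
two conformations (0.4/0.8) despite per-frame noise comparable to their
gap, and the dwell means reflect the 0.1 s⁻¹ exchange rates after the
censoring rules. The other examples cover injection kinetics
(`injection_kinetics.py`), three-color coincidence
(`three_color_coincidence.py` — binding transitions align with the RNA
signal to within one frame, the ALEX resolution limit), solenoid geometry
(`solenoid_geometry.py` — pitch 85 Å vs 43.2 Å, per-junction hinge screws,
FRET-pair screening) and titration fitting (`titration_fit.py`).

For batch work, `pprfret.pipeline.run_pipeline(RunConfig(...))` executes
simulate → calibrate → FRET → denoise → HMM → kinetics and writes all
tables, a JSON summary and a seed-stamped log into a run directory;
reruns of the same config are bit-identical.

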