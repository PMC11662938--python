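# Methods

`pprfret` analyses single-molecule FRET trajectories of a designer
pentatricopeptide-repeat (dPPR) RNA sensor and the structural geometry that
makes the sensor work. This note records the models implemented, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## The physical picture

A dPPR protein is an α-solenoid of ~35-residue repeats, each reading one
ssRNA base. On binding its target the solenoid compacts: per-repeat rise
drops from ~8.5 Å to ~4.8 Å and twist grows from ~36° to ~40°, nearly
halving the superhelical pitch (pitch = rise · 360/twist). A donor/acceptor
pair placed 8 repeats apart therefore moves from outside to inside the
Förster radius (R0 = 54 Å for Cy3/AF647), switching the sensor from a
low-FRET (~0.4) to a high-FRET (~0.8) state. Surface-immobilized sensors
imaged by TIRF at 5 Hz report binding and release of RNA as threshold
crossings of the per-frame FRET efficiency.

## FRET computation and crosstalk

Per frame the approximate efficiency is

    E = CI_A / (CI_A + I_D),   CI_A = I_A − g · I_D,

where g is the donor-into-acceptor leakage constant measured on molecules
carrying only a donor. `estimate_crosstalk` pools the per-frame ratio
(I_A − bg_A)/(I_D − bg_D) over all pre-bleach frames of the donor-only
cohort and takes the median; the background of each channel is the
post-donor-bleach segment mean when a bleach is observed, else zero.
The median is robust to residual steps and outlier frames; the estimate is
invariant to uniform intensity rescaling. E is reported **unclamped** and
frames with a vanishing denominator are flagged non-finite; no gamma or
direct-excitation correction is applied because the ratio is treated as the
approximate efficiency throughout.

## Photobleach detection and molecule selection

Bleach steps are change-points of a penalized piecewise-constant
least-squares fit found by binary segmentation. The penalty is
`3 σ² log n`, with σ a robust noise estimate from median absolute
successive differences; the factor 3 was set so that a ~3σ step persisting
only a few frames is still found (a harsher penalty demonstrably missed
acceptor bleaches with very short bright segments, which then contaminate
downstream dwell statistics), while a noiseless step is always found and an
SNR-5 step is localized within ±1 frame in ≥95% of trials.

Trace-level calls: donor bleach = a persistent drop of the summed intensity
below 30% of the bright level; acceptor bleach = a persistent acceptor drop
(before any donor bleach) to below 18% of the bright level, where only
leakage remains. Traces that never rise above the noise floor ("dark") or
whose acceptor is below leakage from the first frame (no functional FRET
pair) are excluded — these molecules would never pass colocalization in a
real experiment. Selection for cohort statistics keeps molecules with
exactly one donor and one acceptor bleach event and, for molecules showing
candidate transitions, requires donor/acceptor anticorrelation (Pearson
r < 0 by default). This rule is conservative: a release transition
immediately followed by acceptor bleach is counted as two acceptor steps
and rejected. FRET trajectories are truncated at the earliest detected
bleach; untruncated records carry a censored flag.

## NL denoising

The nonlinear forward–backward filter combines trailing and leading
running-mean predictors at window sizes N_FA·f^k (k = 0…n_scales−1). Each
predictor is weighted by its summed squared prediction error over the
trailing (forward) or leading (backward) M frames raised to −p, normalized
to one; predictors with numerically zero error share the weight evenly,
which preserves noiseless steps exactly. Defaults follow the analysis
settings p = 5, N_FA = 1, f = 2; the remaining knobs, which the three
published parameters do not pin down, default to n_scales = 2 and M = 10
and are exposed in `NLFilterParams`. The output is a convex combination of
running means, hence bounded by the input range and idempotent on
constants.

## Variational HMM

Trajectories are idealized with a Gaussian-emission HMM inferred by
variational Bayes: Dirichlet priors on initial and transition probabilities
(concentration 1), and a Normal–Gamma prior on each state's mean and
precision. The two published hyperparameters are mapped as: prior mean
fixed at 0.5 FRET; `mu` (=1.5) is the pseudo-count strength pulling state
means toward it; `beta` (=0.5) multiplies the Gamma rate of the precision
prior, b0 = beta · a0 · σ0², with shape a0 = 2.5 and noise scale σ0 = 0.1
FRET. Both discourage over-fitting: sparsely occupied states collapse to
the prior and contribute no evidence. The exact semantics of the reference
implementation's hyperparameters are not published, so this mapping is a
documented choice and every piece is configurable in `HMMPriors`.

The state count k is selected over k = 1…4 by the variational evidence
(ELBO), 5 restarts per k, restarts seeded deterministically from
(seed, k, restart); ties break toward smaller k. The ELBO is computed
before each M-step and is non-decreasing across iterations (asserted in
tests); convergence at relative tolerance 1e-7, cap 300 iterations with a
best-so-far warning flag. States are reported sorted by ascending mean;
decoding is Viterbi under the expected-log parameters, and
`decode_posteriors` returns forward–backward marginals that match
brute-force path enumeration to 1e-10 on small cases. Non-finite FRET
frames (flagged by the ratio) are replaced by the trace median for fitting
so the decoded path stays frame-aligned. The forward–backward and Viterbi
kernels are JIT-compiled with numba (pure-Python fallback included).

## Kinetics

Idealized values at or above the 0.5 threshold count as high (ties high —
documented tie-break); crossings define T_low-high (binding) and T_high-low
(release), while state changes on one side of the threshold are
within-class and excluded. Residence times are cumulative times on one side
before a crossing, with two censoring rules: the final dwell of every
molecule is deleted (its true extent is unknowable after photobleach
truncation), and dwells shorter than 2·F·N_FA (400 ms at F = 200 ms,
N_FA = 1) are discarded because the denoiser cannot resolve them. Kept,
discarded and deleted parts sum exactly to the imaging lifetime
(conservation, asserted per molecule).

Binding-and-release rates are per-direction crossing counts divided by the
imaging lifetime. The dynamic fraction is the share of molecules showing
both transition classes (optionally among binders only). Time to first
binding is measured from injection to the first T_low-high; molecules that
bleach first are censored and excluded from the reported mean, matching how
observed-event binding times are quoted. Because that estimator is biased
low when photobleaching competes with binding (for exponential waits W and
lifetimes L, E[W | W<L] = 1/(1/μ_W + 1/μ_L)), the cohort summary also
reports the exposure-time MLE — total unbound observation time divided by
the number of events — which is consistent for the generation mean and is
what the recovery tests check. Synchronized transition averages align FRET
in a ±10 s window around T_low-high events whose preceding dwell exceeds
10 s, zero-padding and masking record edges.

## Three-color ALEX

Frames alternate 532/488 nm excitation (even frames 532, frame 0 first), so
the two lasers never share a frame and the minimal resolvable lag between a
FRET^PPR transition and an RNA-signal onset is one original frame;
"same-frame" coincidence is operationalized as |lag| ≤ 1. The total
488-excited fluorescence is the background-subtracted sum of the three
channels, with the background taken per molecule from frames decoded as
unbound; synchronized 488 profiles are max-normalized per molecule (the
published normalization is not specified — flagged as a choice).

## Structural geometry

Per-repeat reference points are Cα centroids of the annotated 35-residue
repeats. The superhelix axis is estimated from cross products of successive
second differences of the centroid sequence (exactly axis-parallel for an
ideal helix), the radius and center from an algebraic circle fit in the
axis-normal plane, and rise/twist as mean axial/angular increments; a
Levenberg–Marquardt polish against the full helix model follows. The
estimator needs ≥4 centroids (two second differences); with 3 a helix is
underdetermined. It is exact on ideal solenoids, invariant to global rigid
motion, and reports the residual centroid RMSD for noisy input. Twist is
reported as a positive angle in (0°, 180°) about the axis oriented from
repeat 1 to N.

Inter-repeat hinge analysis superposes repeat i of conformation A onto
repeat i of B (Kabsch), then expresses the residual transform carrying
repeat i+1 as a screw: rotation angle and axis from the rotation matrix,
axial translation as the axis-parallel component, axis point from the
rank-2 linear system. Recomposition reproduces the transform to machine
precision. FRET-pair screening evaluates all residue pairs at a given
repeat separation in both conformations, retains pairs with
r_apo > R0 > r_bound, and ranks by predicted efficiency contrast
|E_bound − E_apo| with E = 1/(1+(r/R0)⁶). Cα is the default atom for pair
distances, since the atom used for the published distances is not stated.

## Titration

Observed ensemble FRET is fit to the 1:1 ligand-depletion isotherm
fb = ((Kd+S+L) − sqrt((Kd+S+L)² − 4SL))/(2S) by nonlinear least squares in
(Kd, FRET_free, FRET_bound), standard errors from the Jacobian. The
depletion form is used (not a hyperbola) because the sensor concentration
(5 nM) exceeds the Kd (~1 nM). Fits with Kd beyond 10× the sampled range
are flagged non-identifiable; Kd below 1% of the sensor concentration is
flagged near-stoichiometric. Concentrations are nM throughout.

## Synthetic-data generator

The generator emulates: exact continuous-time Markov switching
(Gillespie), camera integration by majority-occupancy frame assignment at
200 ms (the published setting), donor/acceptor rendering with crosstalk
applied forward (donor = I(1−E), acceptor = IE + gI(1−E)), single
irreversible exponential photobleach per dye, solution-injection
experiments (unbound before injection + exponential wait; an 80% stable /
20% dynamic split by default), ALEX three-color rendering, Gaussian
per-channel noise, and ideal solenoid coordinates with congruent per-repeat
pseudo-atom clouds placed by the exact screw motion.

Default conditions: total intensity 1000 a.u., g = 0.07, FRET-equivalent
noise SD 0.08 (per-channel σ = σ_E·I/√(E²+(1−E)²) evaluated at E = 0.5 —
no per-channel SNR is published, so this is a documented choice), unbound/
bound means 0.4/0.8, per-molecule imaging lifetime 120 s (each dye 240 s),
records 120–360 s. Not emulated: EMCCD excess noise and offsets beyond a
constant background, dye blinking (suppressed experimentally by
Trolox/oxygen scavenging), diffusing-background fluorescence, spot overlap
and image registration. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under idealized additive-Gaussian
photophysics, not robustness to every camera artifact of real data.

## Problem sizes

Validation cohorts mirror the emulated experiments at sizes a study of this
kind actually uses: 150-trace state-recovery cohorts (3 seeds), 168- and
150-molecule injection cohorts, a 200-molecule stable/dynamic mixture, 100
titration replicates, 18-repeat solenoids, 10⁴-dwell distributional checks.
These sizes give 3-SEM recovery bands a few percent wide while keeping the
full suite runnable on one CPU in minutes.

## Known limitations

- The dynamic/static classification counts a dynamic molecule as stable if
  it bleaches before its first release; at 120 s lifetimes this inflates
  the stable fraction by a few percentage points.
- The multi-acceptor QC rule can reject a dynamic molecule whose release
  immediately precedes acceptor bleach.
- The mean over uncensored first-binding times is biased low under
  photobleach censoring (quantified above); the exposure-time MLE is
  provided and preferred for recovery claims.
- The HMM assumes Gaussian emissions; the FRET ratio is slightly skewed at
  extreme efficiencies, contributing a ≲0.01 offset at E = 0.8 under the
  default noise.
- Accession-dependent structural checks (real PDB entries) run only when
  the files are present locally; the geometry arm is otherwise validated on
  ideal and constructed models.
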