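"""Canned simulated experiments at the study conditions.

Each function wires the generator defaults to one of the experiment designs
the package emulates (calibrated two-state cohorts, solution-injection
cohorts, stable/dynamic mixtures, titration replicates) and runs the full
analysis chain on the simulated data, returning summary quantities together
with the generation ground truth. Used by the example scripts and the
acceptance machinery; all randomness derives from the single ``seed``.
"""

from __future__ import annotations

import numpy as np

from .denoise import NLFilterParams
from .fretcalc import estimate_crosstalk
from .hmm import HMMPriors
from .kinetics import AnalysisConfig, dynamic_fraction, first_binding_summary
from .pipeline import analyze_traces
from .simulate import (
    InjectionConfig,
    PhotophysicsConfig,
    SolenoidSpec,
    TitrationModel,
    channel_noise_for_fret_sd,
    generate_ideal_solenoid,
    simulate_donor_only_cohort,
    simulate_injection_cohort,
    simulate_titration,
    simulate_two_state_cohort,
    two_state_scheme,
)
from .structure import fit_superhelix
from .titration import fit_kd

__all__ = [
    "study_photophysics",
    "solenoid_parameters",
    "state_recovery_experiment",
    "injection_experiment",
    "stable_dynamic_experiment",
    "titration_replicates",
]

# acquisition constants of the emulated experiment
FRAME_INTERVAL = 0.2  # s (5 Hz camera)
TOTAL_INTENSITY = 1000.0  # a.u. summed dye emission
CROSSTALK_G = 0.07
FRET_NOISE_SD = 0.08
FRET_UNBOUND = 0.4
FRET_BOUND = 0.8
IMAGING_LIFETIME_MEAN = 120.0  # s; exponential, min of the two dye lifetimes


def study_photophysics(
    fret_sd: float = FRET_NOISE_SD,
    g: float = CROSSTALK_G,
    imaging_lifetime_mean: float = IMAGING_LIFETIME_MEAN,
) -> PhotophysicsConfig:
    """Photophysics at the emulated study conditions.

    The per-molecule imaging lifetime (first bleach of either dye) is
    exponential with the given mean, so each dye carries twice that mean.
    """
    return PhotophysicsConfig(
        total_intensity=TOTAL_INTENSITY,
        crosstalk_g=g,
        noise_sd=channel_noise_for_fret_sd(fret_sd, TOTAL_INTENSITY),
        donor_bleach_mean=2.0 * imaging_lifetime_mean,
        acceptor_bleach_mean=2.0 * imaging_lifetime_mean,
    )


def solenoid_parameters(rise: float, twist: float, radius: float = 25.0, n_repeats: int = 18):
    """Generate an ideal solenoid and re-estimate its parameters."""
    spec = SolenoidSpec(rise=rise, twist=twist, radius=radius, n_repeats=n_repeats)
    return fit_superhelix(generate_ideal_solenoid(spec))


def _sub_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]).generate_state(1)[0] & 0x7FFFFFFF)


def state_recovery_experiment(
    seed: int,
    n_traces: int = 150,
    n_donor_only: int = 20,
    constant_level: float | None = None,
    k_on: float = 0.1,
    k_off: float = 0.1,
    duration: float = 120.0,
    denoise: bool = True,
    threshold: float = 0.5,
) -> dict:
    """Calibrated pipeline recovery of the generation FRET levels.

    Renders a cohort (two-state switching by default, or constant at
    ``constant_level``), calibrates crosstalk on a donor-only cohort, runs
    FRET -> truncation -> (NL filter) -> HMM, and pools the idealized frames
    below/above the threshold into the recovered unbound/bound means.
    """
    phys = study_photophysics()
    if constant_level is None:
        scheme = two_state_scheme(FRET_UNBOUND, FRET_BOUND, k_on=k_on, k_off=k_off)
        initial = 0
    else:
        lo, hi = sorted((constant_level, 1.0 - constant_level))
        scheme = two_state_scheme(lo, hi, k_on=0.0, k_off=0.0)
        initial = int(np.argmin(np.abs(scheme.fret_means - constant_level)))
    traces = simulate_two_state_cohort(
        n_traces, scheme, phys, seed=_sub_seed(seed, 1),
        duration=duration, frame_interval=FRAME_INTERVAL, initial_state=initial,
    )
    donly = simulate_donor_only_cohort(
        n_donor_only, phys, seed=_sub_seed(seed, 2),
        duration=duration, frame_interval=FRAME_INTERVAL,
    )
    g_model = estimate_crosstalk(donly)
    _, _, fits = analyze_traces(
        traces,
        g_model,
        NLFilterParams() if denoise else None,
        HMMPriors(),
        AnalysisConfig(),
        seed=_sub_seed(seed, 3),
    )
    low_vals, high_vals = [], []
    for fit in fits:
        ideal = fit.idealized
        low_vals.append(ideal[ideal < threshold])
        high_vals.append(ideal[ideal >= threshold])
    low = np.concatenate(low_vals) if low_vals else np.array([])
    high = np.concatenate(high_vals) if high_vals else np.array([])
    return {
        "g_hat": g_model.g,
        "n_analyzed": len(fits),
        "mean_low": float(low.mean()) if len(low) else float("nan"),
        "mean_high": float(high.mean()) if len(high) else float("nan"),
        "fits": fits,
    }


def injection_experiment(
    seed: int,
    n: int = 168,
    wait_mean: float = 10.6,
    injection_time: float = 10.0,
    duration: float = 360.0,
    fraction_stable: float = 0.8,
) -> dict:
    """Full-pipeline time-to-first-binding on a simulated injection cohort."""
    phys = study_photophysics()
    inj = InjectionConfig(
        injection_time=injection_time,
        wait_mean=wait_mean,
        post_binding_scheme=two_state_scheme(FRET_UNBOUND, FRET_BOUND, k_on=0.1, k_off=0.1),
        fraction_stable=fraction_stable,
    )
    traces = simulate_injection_cohort(
        n, inj, phys, seed=_sub_seed(seed, 4), duration=duration,
        frame_interval=FRAME_INTERVAL,
    )
    _, _, fits = analyze_traces(
        traces, _g_known(), NLFilterParams(), HMMPriors(),
        AnalysisConfig(), seed=_sub_seed(seed, 5),
    )
    summary = first_binding_summary(fits, AnalysisConfig(), injection_time)
    summary["generation_wait_mean"] = wait_mean
    summary["ground_truth_waits"] = np.array([tr.ground_truth.wait_time for tr in traces])
    return summary


def _g_known():
    from .fretcalc import CrosstalkModel

    return CrosstalkModel(CROSSTALK_G)


def stable_dynamic_experiment(
    seed: int,
    n: int = 200,
    fraction_stable: float = 0.8,
    k_off: float = 0.1,
    k_rebind: float = 0.1,
    duration: float = 360.0,
) -> dict:
    """Stable/dynamic classification of a mixed injection cohort.

    Reports the stable percentage among binders: molecules with at least one
    binding event whose fits show no release back across the threshold.
    """
    phys = study_photophysics()
    inj = InjectionConfig(
        injection_time=10.0,
        wait_mean=10.6,
        post_binding_scheme=two_state_scheme(FRET_UNBOUND, FRET_BOUND,
                                             k_on=k_rebind, k_off=k_off),
        fraction_stable=fraction_stable,
    )
    traces = simulate_injection_cohort(
        n, inj, phys, seed=_sub_seed(seed, 6), duration=duration,
        frame_interval=FRAME_INTERVAL,
    )
    _, _, fits = analyze_traces(
        traces, _g_known(), NLFilterParams(), HMMPriors(), AnalysisConfig(),
        seed=_sub_seed(seed, 7),
    )
    dyn = dynamic_fraction(fits, AnalysisConfig(), among_binders=True)
    truth_stable = np.mean([tr.ground_truth.stable for tr in traces])
    return {
        "dynamic_fraction_among_binders": dyn,
        "stable_percent": 100.0 * (1.0 - dyn),
        "generation_stable_percent": 100.0 * float(truth_stable),
        "n_analyzed": len(fits),
    }


def titration_replicates(seed: int, n_replicates: int = 100, kd: float = 1.2,
                         sensor: float = 5.0, noise_sd: float = 0.02) -> dict:
    """Kd recovery over noisy 12-point titration replicates."""
    model = TitrationModel(kd=kd, sensor_conc=sensor, noise_sd=noise_sd)
    rng = np.random.default_rng(_sub_seed(seed, 8))
    kds = []
    for _ in range(n_replicates):
        fit = fit_kd(simulate_titration(model, rng))
        if fit.converged:
            kds.append(fit.kd)
    kds = np.array(kds)
    return {
        "kd_median": float(np.median(kds)),
        "kd_iqr": (float(np.percentile(kds, 25)), float(np.percentile(kds, 75))),
        "n_fits": len(kds),
        "generation_kd": kd,
    }
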