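"""Kinetic analysis of HMM-idealized FRET trajectories.

Transitions are classified by a FRET threshold (default 0.5) into binding
(T_low-high) and release (T_high-low) events; cumulative residence times on
one side of the threshold are extracted with the standard censoring rules
(terminal dwell deleted, dwells shorter than twice the effective averaging
time discarded), and cohort-level quantities (binding-and-release rate,
dynamic fraction, time to first binding, synchronized transition averages,
pooled FRET histograms) are computed from them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HMMFit

__all__ = [
    "AnalysisConfig",
    "Transition",
    "DwellRecord",
    "BindingReleaseRate",
    "FirstBinding",
    "SyncProfile",
    "classify_transitions",
    "residence_times",
    "dwell_accounting",
    "binding_release_rate",
    "dynamic_fraction",
    "time_to_first_binding",
    "first_binding_summary",
    "synchronized_transition_average",
    "collate_histogram",
]

T_LOW_HIGH = "T_low-high"
T_HIGH_LOW = "T_high-low"


@dataclass
class AnalysisConfig:
    """Thresholds and timing used throughout the kinetic analysis.

    ``min_residence_ms`` is fixed by the denoising bandwidth: dwells shorter
    than 2 * F * N_FA (frame interval in ms times the base averaging window)
    cannot be distinguished from filter artefacts and are discarded.
    """

    fret_threshold: float = 0.5
    frame_interval_ms: float = 200.0  # F
    n_fa: int = 1  # base averaging window of the NL filter
    sync_window_s: float = 10.0
    sync_min_residence_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.fret_threshold < 1:
            raise ValueError("fret_threshold must lie in (0, 1)")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be > 0")
        if self.n_fa < 1:
            raise ValueError("n_fa must be >= 1")

    @property
    def min_residence_ms(self) -> float:
        return 2.0 * self.frame_interval_ms * self.n_fa

    @property
    def min_residence_s(self) -> float:
        return self.min_residence_ms / 1000.0


@dataclass
class Transition:
    """A threshold-crossing change of the idealized FRET level."""

    frame: int  # first frame of the arriving state
    f_before: float
    f_after: float

    def __post_init__(self) -> None:
        if self.f_before == self.f_after:
            raise ValueError("transition requires distinct FRET levels")

    def cls(self, threshold: float = 0.5) -> str:
        # a level exactly at the threshold counts as high
        hi_b = self.f_before >= threshold
        hi_a = self.f_after >= threshold
        if hi_b and not hi_a:
            return T_HIGH_LOW
        if not hi_b and hi_a:
            return T_LOW_HIGH
        return "within-class"


@dataclass
class DwellRecord:
    """Cumulative residence on one side of the threshold."""

    molecule_id: str
    cls: str | None  # class of the terminating transition; None if censored
    duration: float  # s
    censored: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("dwell duration must be > 0")
        if self.censored and self.cls is not None:
            raise ValueError("censored dwells carry no class")


def _frame_interval(fit: HMMFit, cfg: AnalysisConfig) -> float:
    dt = fit.frame_interval
    if not math.isfinite(dt):
        dt = cfg.frame_interval_ms / 1000.0
    return dt


def _side(fit: HMMFit, cfg: AnalysisConfig) -> np.ndarray:
    return fit.idealized >= cfg.fret_threshold


def _runs(side: np.ndarray) -> list[tuple[int, int, bool]]:
    """(start, stop, is_high) runs of constant threshold side."""
    out = []
    start = 0
    for i in range(1, len(side) + 1):
        if i == len(side) or side[i] != side[start]:
            out.append((start, i, bool(side[start])))
            start = i
    return out


def classify_transitions(fit: HMMFit, cfg: AnalysisConfig | None = None) -> list[Transition]:
    """Threshold-crossing transitions of the idealized trajectory.

    Consecutive idealized-value changes that stay on one side of the
    threshold (within-class) are excluded; only crossings are returned, in
    frame order.
    """
    cfg = cfg or AnalysisConfig()
    ideal = fit.idealized
    out = []
    side = _side(fit, cfg)
    for t in range(1, len(ideal)):
        if ideal[t] != ideal[t - 1] and side[t] != side[t - 1]:
            out.append(Transition(frame=t, f_before=float(ideal[t - 1]), f_after=float(ideal[t])))
    return out


def all_state_changes(fit: HMMFit) -> list[Transition]:
    """Every idealized-value change, including within-class ones."""
    ideal = fit.idealized
    return [
        Transition(frame=t, f_before=float(ideal[t - 1]), f_after=float(ideal[t]))
        for t in range(1, len(ideal))
        if ideal[t] != ideal[t - 1]
    ]


def dwell_accounting(
    fit: HMMFit, cfg: AnalysisConfig | None = None
) -> tuple[list[DwellRecord], list[float], float]:
    """Full per-molecule dwell bookkeeping.

    Returns (kept dwells, discarded sub-threshold durations, deleted
    terminal-dwell duration); the three parts sum to the trajectory length
    in seconds exactly.
    """
    cfg = cfg or AnalysisConfig()
    dt = _frame_interval(fit, cfg)
    runs = _runs(_side(fit, cfg))
    kept: list[DwellRecord] = []
    discarded: list[float] = []
    terminal = 0.0
    for i, (a, b, is_high) in enumerate(runs):
        dur = (b - a) * dt
        if i == len(runs) - 1:
            # final dwell: truncated by photobleaching, length unknowable
            terminal = dur
            continue
        cls = T_HIGH_LOW if is_high else T_LOW_HIGH
        if dur < cfg.min_residence_s - 1e-12:
            discarded.append(dur)
        else:
            kept.append(DwellRecord(molecule_id=fit.molecule_id, cls=cls, duration=dur))
    return kept, discarded, terminal


def residence_times(
    fit: HMMFit,
    transitions: list[Transition] | None = None,
    cfg: AnalysisConfig | None = None,
) -> list[DwellRecord]:
    """Cumulative residence times terminated by each threshold crossing.

    Consecutive same-side states are merged; the final (photobleach
    truncated) dwell is deleted; dwells shorter than 2 * F * N_FA are
    discarded. ``transitions`` is accepted for interface symmetry and
    consistency checking only - the dwells derive from the same fit.
    """
    cfg = cfg or AnalysisConfig()
    kept, _, _ = dwell_accounting(fit, cfg)
    if transitions is not None:
        n_cross = len([t for t in transitions if t.cls(cfg.fret_threshold) != "within-class"])
        n_runs = len(_runs(_side(fit, cfg))) - 1
        if n_cross != n_runs:
            raise ValueError("transitions do not match the fit's idealized path")
    return kept


@dataclass
class BindingReleaseRate:
    molecule_id: str
    n_binding: int  # T_low-high crossings
    n_release: int  # T_high-low crossings
    imaging_lifetime: float  # s

    @property
    def binding_rate(self) -> float:
        return self.n_binding / self.imaging_lifetime

    @property
    def release_rate(self) -> float:
        return self.n_release / self.imaging_lifetime


def binding_release_rate(fit: HMMFit, cfg: AnalysisConfig | None = None) -> BindingReleaseRate:
    """Threshold crossings per direction divided by the imaging lifetime."""
    cfg = cfg or AnalysisConfig()
    dt = _frame_interval(fit, cfg)
    lifetime = fit.imaging_lifetime
    if not math.isfinite(lifetime):
        lifetime = len(fit.path) * dt
    if lifetime <= 0:
        raise ValueError("imaging lifetime must be > 0")
    trans = classify_transitions(fit, cfg)
    n_bind = sum(1 for t in trans if t.cls(cfg.fret_threshold) == T_LOW_HIGH)
    n_rel = sum(1 for t in trans if t.cls(cfg.fret_threshold) == T_HIGH_LOW)
    return BindingReleaseRate(
        molecule_id=fit.molecule_id,
        n_binding=n_bind,
        n_release=n_rel,
        imaging_lifetime=float(lifetime),
    )


def dynamic_fraction(fits: list[HMMFit], cfg: AnalysisConfig | None = None,
                     among_binders: bool = False) -> float:
    """Fraction of molecules exhibiting both transition classes.

    Molecules with no classified transitions count as static. With
    ``among_binders`` the denominator is restricted to molecules showing at
    least one binding (T_low-high) event.
    """
    cfg = cfg or AnalysisConfig()
    if len(fits) == 0:
        raise ValueError("empty cohort")
    n_dyn = 0
    n_denom = 0
    for fit in fits:
        classes = {t.cls(cfg.fret_threshold) for t in classify_transitions(fit, cfg)}
        is_binder = T_LOW_HIGH in classes
        if among_binders and not is_binder:
            continue
        n_denom += 1
        if T_LOW_HIGH in classes and T_HIGH_LOW in classes:
            n_dyn += 1
    if n_denom == 0:
        raise ValueError("no qualifying molecules in cohort")
    return n_dyn / n_denom


@dataclass
class FirstBinding:
    molecule_id: str
    time: float | None  # s from injection to first T_low-high; None if censored
    exposure: float  # s of observed unbound time after injection

    @property
    def censored(self) -> bool:
        return self.time is None


def time_to_first_binding(
    fit: HMMFit, cfg: AnalysisConfig | None = None, injection_time: float = 10.0
) -> FirstBinding:
    """Time from ligand injection to the first binding transition.

    Molecules that never bind before truncation are censored; ``exposure``
    is the unbound observation time after injection (for rate-based,
    censoring-corrected estimation).
    """
    cfg = cfg or AnalysisConfig()
    dt = _frame_interval(fit, cfg)
    record_end = len(fit.path) * dt
    if injection_time >= record_end:
        return FirstBinding(fit.molecule_id, None, 0.0)
    for t in classify_transitions(fit, cfg):
        if t.cls(cfg.fret_threshold) == T_LOW_HIGH and t.frame * dt >= injection_time:
            tau = t.frame * dt - injection_time
            return FirstBinding(fit.molecule_id, float(tau), float(tau))
    return FirstBinding(fit.molecule_id, None, float(record_end - injection_time))


def first_binding_summary(
    fits: list[HMMFit],
    cfg: AnalysisConfig | None = None,
    injection_time: float = 10.0,
) -> dict:
    """Cohort summary of times to first binding.

    ``mean``/``sem`` are over uncensored molecules (censored ones excluded,
    matching how observed-event binding times are reported);
    ``rate_corrected_mean`` is the exponential exposure-time MLE
    (total exposure / number of events), which corrects for photobleach
    censoring.
    """
    cfg = cfg or AnalysisConfig()
    recs = [time_to_first_binding(f, cfg, injection_time) for f in fits]
    obs = np.array([r.time for r in recs if not r.censored])
    exposure = float(sum(r.exposure for r in recs))
    n_cens = sum(1 for r in recs if r.censored)
    mean = float(obs.mean()) if len(obs) else float("nan")
    sem = float(obs.std(ddof=1) / np.sqrt(len(obs))) if len(obs) > 1 else float("nan")
    return {
        "n": len(recs),
        "n_observed": int(len(obs)),
        "n_censored": int(n_cens),
        "mean": mean,
        "sem": sem,
        "rate_corrected_mean": exposure / len(obs) if len(obs) else float("nan"),
        "times": obs,
    }


@dataclass
class SyncProfile:
    """Per-event FRET matrix aligned at T_low-high transitions."""

    matrix: np.ndarray  # (n_events, 2*w) FRET, zero-padded at edges
    mask: np.ndarray  # True where padded
    lag_s: np.ndarray  # time relative to the transition, s
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]


def synchronized_transition_average(
    fits: list[HMMFit],
    series: list[np.ndarray],
    cfg: AnalysisConfig | None = None,
) -> SyncProfile:
    """FRET in a +/- window around qualifying binding transitions.

    Only T_low-high events whose preceding (low) residence exceeds
    ``sync_min_residence_s`` qualify; events nearer than the window to the
    record edges are zero-padded and masked. ``series`` supplies the FRET
    values to average (raw or denoised), aligned frame-by-frame with each
    fit.
    """
    cfg = cfg or AnalysisConfig()
    if len(fits) != len(series):
        raise ValueError("fits and series must pair up")
    rows, masks = [], []
    w = None
    dt_ref = None
    for fit, y in zip(fits, series):
        y = np.asarray(y, dtype=float)
        if len(y) != len(fit.path):
            raise ValueError(f"series length mismatch for {fit.molecule_id}")
        dt = _frame_interval(fit, cfg)
        if w is None:
            dt_ref = dt
            w = int(round(cfg.sync_window_s / dt))
        runs = _runs(_side(fit, cfg))
        for i in range(1, len(runs)):
            a, b, is_high = runs[i]
            pa, pb, p_high = runs[i - 1]
            if not is_high or p_high:
                continue  # not a T_low-high
            if (pb - pa) * dt <= cfg.sync_min_residence_s:
                continue
            row = np.zeros(2 * w)
            msk = np.ones(2 * w, dtype=bool)
            lo = max(a - w, 0)
            hi = min(a + w, len(y))
            row[w - (a - lo) : w + (hi - a)] = y[lo:hi]
            msk[w - (a - lo) : w + (hi - a)] = False
            rows.append(row)
            masks.append(msk)
    if w is None:
        w = int(round(cfg.sync_window_s / (cfg.frame_interval_ms / 1000.0)))
        dt_ref = cfg.frame_interval_ms / 1000.0
    lag = (np.arange(2 * w) - w) * dt_ref
    if not rows:
        empty = np.zeros((0, 2 * w))
        return SyncProfile(empty, np.zeros((0, 2 * w), bool), lag,
                           np.full(2 * w, np.nan), np.full(2 * w, np.nan))
    M = np.vstack(rows)
    K = np.vstack(masks)
    mm = np.ma.masked_array(M, mask=K)
    return SyncProfile(M, K, lag, np.asarray(mm.mean(axis=0)), np.asarray(mm.std(axis=0)))


def collate_histogram(
    trajectories, bins: int = 70, value_range: tuple = (-0.2, 1.2)
) -> pd.DataFrame:
    """Pooled per-frame FRET histogram (count and density-normalized).

    All datapoints of all molecules are collated; the density column
    integrates to 1 over the histogram range.
    """
    vals = []
    for tj in trajectories:
        y = np.asarray(getattr(tj, "fret", tj), dtype=float)
        vals.append(y[np.isfinite(y)])
    if not vals:
        raise ValueError("no trajectories given")
    pooled = np.concatenate(vals)
    counts, edges = np.histogram(pooled, bins=bins, range=value_range)
    density, _ = np.histogram(pooled, bins=bins, range=value_range, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "count": counts, "density": density})
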