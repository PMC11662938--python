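"""Crosstalk calibration, FRET computation and photobleach-based QC.

FRET efficiency per frame is the crosstalk-corrected ratio

    E = CI_A / (CI_A + I_D),   CI_A = I_A - g * I_D,

where g is the donor-into-acceptor leakage constant calibrated on
donor-only molecules. Trajectories are truncated at the earliest detected
photobleach; molecule selection mirrors single-molecule practice (single
donor and single acceptor bleach event, anticorrelated channel changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LASER_GREEN, FRETTrajectory, RawTrace, TraceSet

__all__ = [
    "CrosstalkModel",
    "StepEvent",
    "BleachCall",
    "QCCriteria",
    "estimate_crosstalk",
    "compute_fret",
    "detect_photobleach_steps",
    "locate_bleach",
    "truncate_at_photobleach",
    "select_molecules",
]


@dataclass
class CrosstalkModel:
    """Single-constant donor->acceptor leakage model."""

    g: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("crosstalk constant g must be >= 0")


@dataclass
class StepEvent:
    """A change-point of a piecewise-constant intensity fit."""

    frame: int  # first frame of the new level
    magnitude: float  # mean(after) - mean(before)

    @property
    def sign(self) -> int:
        return 1 if self.magnitude > 0 else -1


# ---------------------------------------------------------------------------
# change-point detection (penalized least squares, binary segmentation)


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute successive difference (robust to
    steps and slow drift)."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _binary_segmentation(x: np.ndarray, penalty: float, min_size: int = 2) -> list[int]:
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(a: int, b: int) -> float:  # segment [a, b)
        s = c1[b] - c1[a]
        q = c2[b] - c2[a]
        return q - s * s / (b - a)

    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        ms = np.arange(a + min_size, b - min_size + 1)
        if len(ms) == 0:
            continue
        sl = c1[ms] - c1[a]
        ql = c2[ms] - c2[a]
        sr = c1[b] - c1[ms]
        qr = c2[b] - c2[ms]
        cost = (ql - sl * sl / (ms - a)) + (qr - sr * sr / (b - ms))
        j = int(np.argmin(cost))
        gain = sse(a, b) - cost[j]
        if gain > penalty:
            m = int(ms[j])
            cps.append(m)
            stack.append((a, m))
            stack.append((m, b))
    return sorted(cps)


def detect_photobleach_steps(
    series,
    sensitivity: float = 3.0,
    penalty_factor: float = 3.0,
    direction: str = "down",
    min_size: int = 2,
) -> list[StepEvent]:
    """Detect intensity steps via a penalized piecewise-constant fit.

    Change-points are found by binary segmentation of the least-squares cost
    with penalty ``penalty_factor * sigma^2 * log(n)`` (sigma = robust noise
    estimate from successive differences; a noiseless step is therefore
    always found). Steps larger than ``sensitivity * sigma`` are reported in
    frame order; ``direction`` selects "down", "up" or "both".
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series too short for step detection (need >= 10 frames)")
    sigma = _robust_noise_sd(x)
    scale = max(np.ptp(x), 1.0)
    sigma_eff = max(sigma, 1e-9 * scale)
    penalty = penalty_factor * sigma_eff**2 * np.log(len(x))
    cps = _binary_segmentation(x, penalty, min_size=min_size)
    bounds = [0, *cps, len(x)]
    means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    events = []
    for i, cp in enumerate(cps):
        mag = means[i + 1] - means[i]
        if abs(mag) <= sensitivity * sigma:
            continue
        if direction == "down" and mag >= 0:
            continue
        if direction == "up" and mag <= 0:
            continue
        events.append(StepEvent(frame=cp, magnitude=float(mag)))
    return events


# ---------------------------------------------------------------------------
# bleach localization


@dataclass
class BleachCall:
    """Detected bleach structure of a two-color trace."""

    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    donor_candidates: list = field(default_factory=list)
    acceptor_candidates: list = field(default_factory=list)
    bright_level: float = 0.0
    dark: bool = False  # no fluorophore signal above the noise floor
    acceptor_dead: bool = False  # acceptor never above leakage: not a FRET pair

    @property
    def truncation_frame(self) -> int | None:
        frames = [f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame) if f is not None]
        return min(frames) if frames else None


def _segment_means(x: np.ndarray, cps: list[int]) -> tuple[list, list]:
    bounds = [0, *cps, len(x)]
    means = [float(x[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    return bounds, means


def locate_bleach(
    trace: RawTrace,
    donor_dark_frac: float = 0.3,
    acceptor_dark_frac: float = 0.18,
    acceptor_step_frac: float = 0.25,
    penalty_factor: float = 3.0,
) -> BleachCall:
    """Locate donor and acceptor photobleach frames in a two-color trace.

    Donor bleach: a downward step of the summed (donor + acceptor) intensity
    to below ``donor_dark_frac`` of the bright level that persists to the end
    of the record. Acceptor bleach: a persistent downward acceptor step,
    before any donor bleach, that leaves the acceptor channel below
    ``acceptor_dark_frac`` of the bright level (only leakage remains).
    Acceptor candidates additionally include persistent large drops that do
    not recover, so multi-acceptor staircases are counted.
    """
    m532 = trace.laser == LASER_GREEN
    donor = trace.donor[m532]
    acceptor = trace.acceptor[m532]
    orig = np.flatnonzero(m532)
    total = donor + acceptor
    n = len(total)
    if n < 10:
        raise ValueError("trace too short for bleach localization")
    p95 = np.percentile(total, 95)
    bright = total > 0.5 * p95
    level = float(np.median(total[bright])) if bright.any() else float(np.median(total))

    sigma_t = _robust_noise_sd(total)
    if p95 - np.median(total) < 3.0 * sigma_t and p95 < 5.0 * sigma_t:
        # never rises above the noise floor: no analyzable fluorophore pair
        return BleachCall(None, None, bright_level=level, dark=True)
    pen = penalty_factor * max(sigma_t, 1e-9 * max(level, 1.0)) ** 2 * np.log(n)
    cps_t = _binary_segmentation(total, pen)
    bounds_t, means_t = _segment_means(total, cps_t)

    donor_candidates = []
    for i, cp in enumerate(cps_t):
        pre, post = means_t[i], means_t[i + 1]
        persists = all(m < 0.5 * level for m in means_t[i + 1 :])
        if pre > 0.5 * level and post < donor_dark_frac * level and persists:
            donor_candidates.append(int(cp))
    donor_bf = donor_candidates[0] if len(donor_candidates) == 1 else (
        donor_candidates[0] if donor_candidates else None
    )

    sigma_a = _robust_noise_sd(acceptor)
    pen_a = penalty_factor * max(sigma_a, 1e-9 * max(level, 1.0)) ** 2 * np.log(n)
    cps_a = _binary_segmentation(acceptor, pen_a)
    _, means_a = _segment_means(acceptor, cps_a)
    stop = donor_bf if donor_bf is not None else n
    acceptor_candidates = []
    acceptor_bf = None
    for i, cp in enumerate(cps_a):
        if cp >= stop:
            continue
        pre, post = means_a[i], means_a[i + 1]
        later = [m for c, m in zip(cps_a[i + 1 :], means_a[i + 2 :]) if c < stop]
        recovers = any(m > pre - 0.15 * level for m in later)
        big_drop = (pre - post) > acceptor_step_frac * level
        dark = post < acceptor_dark_frac * level
        if recovers or not (big_drop or dark):
            continue
        acceptor_candidates.append(int(cp))
        if dark and acceptor_bf is None:
            acceptor_bf = int(cp)

    # acceptor never above the leakage level before donor bleach: the
    # molecule carries no functional acceptor (not a FRET pair)
    pre_means = [m for bnd, m in zip([0, *cps_a], means_a) if bnd < stop]
    acceptor_dead = bool(pre_means) and all(
        m < acceptor_dark_frac * level for m in pre_means
    )

    # map back to original frame indices (identity for pure two-color traces)
    def _map(f):
        return int(orig[f]) if f is not None else None

    return BleachCall(
        donor_bleach_frame=_map(donor_bf),
        acceptor_bleach_frame=_map(acceptor_bf),
        donor_candidates=[_map(f) for f in donor_candidates],
        acceptor_candidates=sorted({_map(f) for f in acceptor_candidates}),
        bright_level=level,
        acceptor_dead=acceptor_dead,
    )


# ---------------------------------------------------------------------------
# crosstalk and FRET


def estimate_crosstalk(donor_only_traces: TraceSet | list) -> CrosstalkModel:
    """Calibrate g on donor-only molecules.

    g is the pooled median over pre-bleach frames of
    (acceptor - background) / (donor - background); the background of each
    channel is the post-donor-bleach segment mean when a bleach is observed
    (else 0).
    """
    ratios = []
    for tr in donor_only_traces:
        m532 = tr.laser == LASER_GREEN
        donor = tr.donor[m532]
        acceptor = tr.acceptor[m532]
        if not np.any(np.abs(donor) > 0):
            continue
        try:
            call = locate_bleach(tr)
        except ValueError:
            call = BleachCall(None, None)
        bf = call.donor_bleach_frame
        if bf is not None and len(donor) - bf >= 5:
            bg_d = float(donor[bf:].mean())
            bg_a = float(acceptor[bf:].mean())
            pre = slice(0, bf)
        else:
            bg_d = bg_a = 0.0
            pre = slice(0, len(donor))
        d = donor[pre] - bg_d
        a = acceptor[pre] - bg_a
        floor = 0.25 * np.median(d) if np.median(d) > 0 else 0.0
        ok = d > max(floor, 1e-12)
        ratios.append(a[ok] / d[ok])
    if not ratios:
        raise ValueError("crosstalk undefined: no usable donor signal in input traces")
    pooled = np.concatenate(ratios)
    if len(pooled) == 0:
        raise ValueError("crosstalk undefined: no pre-bleach frames with donor signal")
    return CrosstalkModel(g=max(float(np.median(pooled)), 0.0))


def compute_fret(trace: RawTrace, model: CrosstalkModel) -> FRETTrajectory:
    """Per-frame crosstalk-corrected FRET efficiency (532-nm frames only).

    Values are reported unclamped; frames with a vanishing denominator are
    non-finite and flagged. Three-color traces must be demultiplexed first.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if np.any(trace.laser != LASER_GREEN):
        raise ValueError("compute_fret expects 532-nm frames only; demultiplex ALEX traces first")
    ci = trace.acceptor - model.g * trace.donor
    denom = ci + trace.donor
    with np.errstate(divide="ignore", invalid="ignore"):
        fret = ci / denom
    return FRETTrajectory(
        molecule_id=trace.molecule_id,
        fret=fret,
        frame_interval=trace.frame_interval,
        truncation_frame=len(trace),
        censored=True,
    )


def truncate_at_photobleach(
    traj: FRETTrajectory, call: BleachCall | int | None
) -> FRETTrajectory:
    """Truncate a trajectory at the earliest detected bleach frame.

    ``call`` may be a :class:`BleachCall` or a frame index; ``None`` (or a
    call without any bleach) keeps the full record and sets the censored
    flag. A bleach at frame 0 leaves no usable frames and raises.
    """
    if isinstance(call, BleachCall):
        frame = call.truncation_frame
    else:
        frame = call
    if frame is None:
        return FRETTrajectory(
            molecule_id=traj.molecule_id,
            fret=traj.fret.copy(),
            frame_interval=traj.frame_interval,
            truncation_frame=len(traj.fret),
            censored=True,
        )
    if frame <= 0:
        raise ValueError("photobleach at frame 0 leaves an empty trajectory")
    frame = min(frame, len(traj.fret))
    return FRETTrajectory(
        molecule_id=traj.molecule_id,
        fret=traj.fret[:frame].copy(),
        frame_interval=traj.frame_interval,
        truncation_frame=frame,
        censored=False,
    )


# ---------------------------------------------------------------------------
# molecule selection


@dataclass
class QCCriteria:
    """Selection rules for FRET-competent single molecules."""

    anticorrelation_ceiling: float = 0.0  # Pearson r of donor vs acceptor
    min_prebleach_frames: int = 10


def _candidate_transitions(trace: RawTrace, call: BleachCall) -> int:
    """Count anticorrelated step pairs before truncation (potential
    conformational transitions), excluding the bleach steps themselves."""
    stop = call.truncation_frame or len(trace)
    m532 = trace.laser == LASER_GREEN
    donor = trace.donor[m532][:stop]
    acceptor = trace.acceptor[m532][:stop]
    if len(donor) < 10:
        return 0
    try:
        sd = detect_photobleach_steps(donor, direction="both")
        sa = detect_photobleach_steps(acceptor, direction="both")
    except ValueError:
        return 0
    bleach_frames = set(
        f for f in (call.donor_bleach_frame, call.acceptor_bleach_frame) if f is not None
    )
    count = 0
    for ed in sd:
        for ea in sa:
            if abs(ed.frame - ea.frame) <= 1 and ed.sign != ea.sign:
                if ed.frame not in bleach_frames and ea.frame not in bleach_frames:
                    count += 1
                break
    return count


def select_molecules(
    traces: TraceSet, criteria: QCCriteria | None = None
) -> tuple[TraceSet, pd.DataFrame]:
    """Keep molecules with a single donor and a single acceptor bleach event.

    The anticorrelation criterion (Pearson correlation of donor vs acceptor
    over pre-bleach frames below ``anticorrelation_ceiling``) is applied only
    to molecules whose trajectory contains at least one candidate transition.
    Returns the accepted subset plus a per-molecule QC report.
    """
    criteria = criteria or QCCriteria()
    rows = []
    kept = []
    for tr in traces:
        reasons = []
        try:
            call = locate_bleach(tr)
        except ValueError as exc:
            rows.append({"molecule_id": tr.molecule_id, "accepted": False, "reason": str(exc)})
            continue
        if call.dark:
            rows.append({"molecule_id": tr.molecule_id, "accepted": False, "reason": "dark"})
            continue
        nd = len(call.donor_candidates)
        na = len(call.acceptor_candidates)
        if nd == 0:
            reasons.append("no-donor-bleach")
        elif nd > 1:
            reasons.append("multi-donor")
        if na == 0:
            reasons.append("no-acceptor-bleach")
        elif na > 1:
            reasons.append("multi-acceptor")
        stop = call.truncation_frame or len(tr)
        if stop < criteria.min_prebleach_frames:
            reasons.append("too-few-prebleach-frames")
        elif _candidate_transitions(tr, call) >= 1:
            m532 = tr.laser == LASER_GREEN
            d = tr.donor[m532][:stop]
            a = tr.acceptor[m532][:stop]
            r = float(np.corrcoef(d, a)[0, 1]) if d.std() > 0 and a.std() > 0 else 0.0
            if not r < criteria.anticorrelation_ceiling:
                reasons.append("not-anticorrelated")
        ok = not reasons
        rows.append(
            {
                "molecule_id": tr.molecule_id,
                "accepted": ok,
                "reason": ";".join(reasons) if reasons else "",
                "donor_bleach_frame": call.donor_bleach_frame,
                "acceptor_bleach_frame": call.acceptor_bleach_frame,
            }
        )
        if ok:
            kept.append(tr)
    return TraceSet(kept), pd.DataFrame(rows)
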