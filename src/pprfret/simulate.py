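"""Forward simulation of smFRET experiments with known ground truth.

The generator emulates the acquisition model of a TIRF experiment on
surface-immobilized, dual-labeled designer PPR molecules: a continuous-time
Markov jump process over conformational states (unbound ~0.4 FRET, RNA-bound
~0.8), camera integration at a fixed frame interval (majority-occupancy state
assignment), donor->acceptor spectral crosstalk ``g``, additive Gaussian
detection noise per channel, single-step exponential photobleaching of each
dye, solution-injection experiments with exponential times to first binding,
three-color alternating-laser (ALEX) rendering, ensemble titration curves
under ligand depletion, and ideal alpha-solenoid coordinate models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import LASER_BLUE, LASER_GREEN, RawTrace, TraceGroundTruth, TraceSet
from .structure import CoordinateSet
from .titration import TitrationCurve, bound_fraction

__all__ = [
    "KineticScheme",
    "PhotophysicsConfig",
    "InjectionConfig",
    "TitrationModel",
    "SolenoidSpec",
    "StatePath",
    "simulate_state_path",
    "render_two_color",
    "render_three_color",
    "simulate_injection_cohort",
    "simulate_two_state_cohort",
    "simulate_donor_only_cohort",
    "simulate_titration",
    "generate_ideal_solenoid",
    "channel_noise_for_fret_sd",
    "two_state_scheme",
]


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class KineticScheme:
    """Conformational states, their FRET means and pairwise exchange rates.

    ``rates[i, j]`` is the transition rate i -> j in 1/s (diagonal ignored).
    ``bound_states`` marks which states correspond to the RNA-bound protein;
    by default any state with FRET mean >= 0.5 counts as bound.
    """

    state_labels: tuple
    fret_means: np.ndarray
    rates: np.ndarray
    bound_states: tuple | None = None

    def __post_init__(self) -> None:
        self.fret_means = np.atleast_1d(np.asarray(self.fret_means, dtype=float))
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        k = len(self.state_labels)
        if k < 1:
            raise ValueError("at least one state required")
        if self.fret_means.shape != (k,):
            raise ValueError("fret_means length must match state_labels")
        if np.any((self.fret_means < 0) | (self.fret_means > 1)):
            raise ValueError("fret_means must lie in [0, 1]")
        if self.rates.shape != (k, k):
            raise ValueError("rates must be a KxK matrix")
        off = self.rates[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("transition rates must be >= 0")
        if self.bound_states is None:
            self.bound_states = tuple(
                lab for lab, e in zip(self.state_labels, self.fret_means) if e >= 0.5
            )

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def bound_mask(self) -> np.ndarray:
        return np.array([lab in self.bound_states for lab in self.state_labels])


def two_state_scheme(
    fret_unbound: float = 0.4,
    fret_bound: float = 0.8,
    k_on: float = 0.0,
    k_off: float = 0.0,
) -> KineticScheme:
    """Convenience two-state (unbound/bound) scheme."""
    return KineticScheme(
        state_labels=("unbound", "bound"),
        fret_means=np.array([fret_unbound, fret_bound]),
        rates=np.array([[0.0, k_on], [k_off, 0.0]]),
    )


@dataclass
class PhotophysicsConfig:
    """Emission intensities, crosstalk, noise and photobleach lifetimes.

    Intensities are in arbitrary camera units; bleach lifetimes are the means
    of the single irreversible exponential bleach event per dye (``inf`` for
    a dye that never bleaches within the record). ``blue_fractions`` splits
    the blue-excited total intensity over the (blue, donor, acceptor)
    detection channels when the labeled RNA is bound.
    """

    total_intensity: float = 1000.0
    crosstalk_g: float = 0.07
    noise_sd: float = 0.0
    background: float = 0.0
    donor_bleach_mean: float = math.inf
    acceptor_bleach_mean: float = math.inf
    blue_bleach_mean: float = math.inf
    blue_total_intensity: float | None = None
    blue_fractions: tuple = (0.4, 0.3, 0.3)

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if self.crosstalk_g < 0:
            raise ValueError("crosstalk_g must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for m in (self.donor_bleach_mean, self.acceptor_bleach_mean, self.blue_bleach_mean):
            if m <= 0:
                raise ValueError("bleach lifetimes must be > 0")
        if self.blue_total_intensity is None:
            self.blue_total_intensity = self.total_intensity


@dataclass
class InjectionConfig:
    """Solution-injection experiment: ligand arrives at ``injection_time``.

    Each molecule stays unbound until ``injection_time`` plus an exponential
    wait of mean ``wait_mean``; a ``fraction_stable`` subset then binds
    irreversibly while the remainder follows ``post_binding_scheme``.
    """

    injection_time: float = 10.0
    wait_mean: float = 10.6
    post_binding_scheme: KineticScheme = field(
        default_factory=lambda: two_state_scheme(k_on=0.1, k_off=0.1)
    )
    fraction_stable: float = 0.8

    def __post_init__(self) -> None:
        if self.injection_time < 0:
            raise ValueError("injection_time must be >= 0")
        if self.wait_mean <= 0:
            raise ValueError("wait_mean must be > 0")
        if not 0 <= self.fraction_stable <= 1:
            raise ValueError("fraction_stable must lie in [0, 1]")


@dataclass
class TitrationModel:
    """Ground truth for an ensemble FRET titration with ligand depletion."""

    kd: float = 1.2  # nM
    sensor_conc: float = 5.0  # nM
    ligand_concs: np.ndarray = field(
        default_factory=lambda: np.geomspace(1000.0, 0.01, 12)
    )
    fret_free: float = 0.3
    fret_bound: float = 0.7
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        if self.kd < 0:
            raise ValueError("kd must be >= 0")
        if self.sensor_conc <= 0:
            raise ValueError("sensor_conc must be > 0")
        if np.any(self.ligand_concs <= 0):
            raise ValueError("ligand concentrations must be > 0")
        if not self.fret_free < self.fret_bound:
            raise ValueError("fret_free must be < fret_bound")


@dataclass
class SolenoidSpec:
    """Idealized alpha-solenoid superhelix: one reference point per repeat."""

    rise: float  # Angstrom per repeat
    twist: float  # degrees per repeat
    radius: float  # Angstrom
    n_repeats: int = 18

    def __post_init__(self) -> None:
        if not 0 < self.twist < 180:
            raise ValueError("twist must lie in (0, 180) degrees")
        if self.n_repeats < 3:
            raise ValueError("n_repeats must be >= 3")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


# ---------------------------------------------------------------------------
# state-path simulation


@dataclass
class StatePath:
    """Per-frame state labels plus the exact continuous-time jump record."""

    states: np.ndarray  # per-frame state index
    frame_interval: float
    duration: float
    jump_times: np.ndarray  # instants of state change, s
    jump_states: np.ndarray  # state entered at each jump
    initial_state: int
    fret_means: np.ndarray  # per-state FRET used downstream
    bound: np.ndarray  # per-state RNA-bound flag

    def __len__(self) -> int:
        return len(self.states)

    def dwell_times(self) -> np.ndarray:
        """Ground-truth dwell durations of the continuous-time path
        (completed dwells only; the final, duration-censored dwell is
        excluded)."""
        ts = np.concatenate([[0.0], self.jump_times])
        return np.diff(ts)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _discretize_segments(segments, n_states: int, duration: float, dt: float) -> np.ndarray:
    """Majority-occupancy state per frame from (t0, t1, state) segments."""
    n_frames = int(round(duration / dt))
    occ = np.zeros((n_frames, n_states))
    for t0, t1, s in segments:
        t1 = min(t1, duration)
        if t1 <= t0:
            continue
        i0 = int(t0 / dt)
        i1 = min(int(np.ceil(t1 / dt)), n_frames)
        idx = np.arange(i0, i1)
        lo = np.maximum(t0, idx * dt)
        hi = np.minimum(t1, (idx + 1) * dt)
        occ[idx, s] += hi - lo
    return occ.argmax(axis=1)


def _gillespie(scheme: KineticScheme, duration: float, rng, start: int, t_offset=0.0):
    """Exact continuous-time Markov jump sequence on [t_offset, t_offset+duration)."""
    jumps_t, jumps_s = [], []
    segments = []
    t, s = 0.0, start
    rates = scheme.rates.copy()
    np.fill_diagonal(rates, 0.0)
    while True:
        exit_rate = rates[s].sum()
        if exit_rate <= 0:
            segments.append((t_offset + t, t_offset + duration, s))
            break
        dt = rng.exponential(1.0 / exit_rate)
        if t + dt >= duration:
            segments.append((t_offset + t, t_offset + duration, s))
            break
        segments.append((t_offset + t, t_offset + t + dt, s))
        t += dt
        s = int(rng.choice(scheme.n_states, p=rates[s] / exit_rate))
        jumps_t.append(t_offset + t)
        jumps_s.append(s)
    return segments, np.array(jumps_t), np.array(jumps_s, dtype=int)


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    frame_interval: float,
    seed,
    initial_state: int = 0,
) -> StatePath:
    """Simulate the conformational path and discretize it to frames.

    Exact jump times are drawn by the Gillespie algorithm; each camera frame
    is assigned the state occupying the majority of its integration window.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = _rng(seed)
    segments, jt, js = _gillespie(scheme, duration, rng, initial_state)
    states = _discretize_segments(segments, scheme.n_states, duration, frame_interval)
    return StatePath(
        states=states,
        frame_interval=frame_interval,
        duration=duration,
        jump_times=jt,
        jump_states=js,
        initial_state=initial_state,
        fret_means=scheme.fret_means.copy(),
        bound=scheme.bound_mask,
    )


# ---------------------------------------------------------------------------
# rendering


def _bleach_frame(mean: float, dt: float, n_frames: int, rng) -> int | None:
    if not math.isfinite(mean):
        return None
    t = rng.exponential(mean)
    f = int(t / dt)
    return f if f < n_frames else None


def render_two_color(
    path: StatePath, phys: PhotophysicsConfig, seed, molecule_id: str = "mol0"
) -> RawTrace:
    """Render donor/acceptor intensities from a state path.

    Before any bleach: donor = I(1-E), acceptor = IE + gI(1-E). After the
    acceptor bleaches all emission returns to the donor (donor = I, acceptor
    sees only leakage gI); after the donor bleaches both channels fall to
    background. Gaussian noise and a constant background offset are added to
    every channel at every frame.
    """
    if len(path) == 0:
        raise ValueError("state path is empty")
    rng = _rng(seed)
    n = len(path)
    dt = path.frame_interval
    I = phys.total_intensity
    g = phys.crosstalk_g
    E = path.fret_means[path.states]

    donor = I * (1.0 - E)
    acceptor = I * E + g * I * (1.0 - E)

    db = _bleach_frame(phys.donor_bleach_mean, dt, n, rng)
    ab = _bleach_frame(phys.acceptor_bleach_mean, dt, n, rng)
    if ab is not None:
        sel = np.arange(n) >= ab
        donor[sel] = I
        acceptor[sel] = g * I
    if db is not None:
        sel = np.arange(n) >= db
        donor[sel] = 0.0
        acceptor[sel] = 0.0

    donor = donor + phys.background
    acceptor = acceptor + phys.background
    if phys.noise_sd > 0:
        donor = donor + rng.normal(0.0, phys.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, phys.noise_sd, n)

    gt = TraceGroundTruth(
        frame_states=path.states.copy(),
        jump_times=path.jump_times.copy(),
        jump_states=path.jump_states.copy(),
        fret_means=path.fret_means.copy(),
        donor_bleach_frame=db,
        acceptor_bleach_frame=ab,
    )
    return RawTrace(
        molecule_id=molecule_id,
        time_s=np.arange(n) * dt,
        donor=donor,
        acceptor=acceptor,
        ground_truth=gt,
    )


def default_alex_scheme(n_frames: int) -> np.ndarray:
    """Frame-parity ALEX mapping: even frames 532 nm, odd frames 488 nm."""
    laser = np.where(np.arange(n_frames) % 2 == 0, LASER_GREEN, LASER_BLUE)
    return laser


def render_three_color(
    path: StatePath,
    phys: PhotophysicsConfig,
    alex_scheme: np.ndarray | None = None,
    seed=0,
    molecule_id: str = "mol0",
) -> RawTrace:
    """Render a three-color ALEX trace (532/488 alternation).

    532-frames follow the two-color model. On 488-frames the blue-excited
    total intensity is split over the (blue, donor, acceptor) channels while
    the labeled RNA is bound and its dye unbleached; otherwise all three
    channels carry only background and noise.
    """
    if len(path) == 0:
        raise ValueError("state path is empty")
    rng = _rng(seed)
    n = len(path)
    dt = path.frame_interval
    laser = default_alex_scheme(n) if alex_scheme is None else np.asarray(alex_scheme)
    if laser.shape != (n,):
        raise ValueError("alex_scheme must assign a laser to every frame")

    I = phys.total_intensity
    g = phys.crosstalk_g
    E = path.fret_means[path.states]
    bound = path.bound[path.states]

    donor = I * (1.0 - E)
    acceptor = I * E + g * I * (1.0 - E)
    blue = np.zeros(n)

    db = _bleach_frame(phys.donor_bleach_mean, dt, n, rng)
    ab = _bleach_frame(phys.acceptor_bleach_mean, dt, n, rng)
    bb = _bleach_frame(phys.blue_bleach_mean, dt, n, rng)
    if ab is not None:
        sel = np.arange(n) >= ab
        donor[sel] = I
        acceptor[sel] = g * I
    if db is not None:
        sel = np.arange(n) >= db
        donor[sel] = 0.0
        acceptor[sel] = 0.0

    is488 = laser == LASER_BLUE
    blue_on = bound.copy()
    if bb is not None:
        blue_on[np.arange(n) >= bb] = False
    fb, fd, fa = phys.blue_fractions
    Ib = phys.blue_total_intensity
    donor[is488] = np.where(blue_on[is488], fd * Ib, 0.0)
    acceptor[is488] = np.where(blue_on[is488], fa * Ib, 0.0)
    blue[is488] = np.where(blue_on[is488], fb * Ib, 0.0)

    for ch in (donor, acceptor, blue):
        ch += phys.background
    if phys.noise_sd > 0:
        donor = donor + rng.normal(0.0, phys.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, phys.noise_sd, n)
        blue = blue + rng.normal(0.0, phys.noise_sd, n)

    gt = TraceGroundTruth(
        frame_states=path.states.copy(),
        jump_times=path.jump_times.copy(),
        jump_states=path.jump_states.copy(),
        fret_means=path.fret_means.copy(),
        donor_bleach_frame=db,
        acceptor_bleach_frame=ab,
        blue_bleach_frame=bb,
    )
    return RawTrace(
        molecule_id=molecule_id,
        time_s=np.arange(n) * dt,
        donor=donor,
        acceptor=acceptor,
        blue=blue,
        laser=laser,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# cohorts


def _injection_path(
    inj: InjectionConfig, duration: float, dt: float, rng
) -> tuple[StatePath, float, bool]:
    scheme = inj.post_binding_scheme
    unbound = int(np.argmin(scheme.fret_means))
    bound = int(np.argmax(scheme.fret_means))
    wait = rng.exponential(inj.wait_mean)
    t_bind = inj.injection_time + wait
    stable = bool(rng.random() < inj.fraction_stable)

    segments = [(0.0, min(t_bind, duration), unbound)]
    jt: np.ndarray = np.array([])
    js: np.ndarray = np.array([], dtype=int)
    if t_bind < duration:
        jt = np.array([t_bind])
        js = np.array([bound], dtype=int)
        if stable:
            segments.append((t_bind, duration, bound))
        else:
            post_seg, post_jt, post_js = _gillespie(
                scheme, duration - t_bind, rng, bound, t_offset=t_bind
            )
            segments.extend(post_seg)
            jt = np.concatenate([jt, post_jt])
            js = np.concatenate([js, post_js])
    states = _discretize_segments(segments, scheme.n_states, duration, dt)
    path = StatePath(
        states=states,
        frame_interval=dt,
        duration=duration,
        jump_times=jt,
        jump_states=js,
        initial_state=unbound,
        fret_means=scheme.fret_means.copy(),
        bound=scheme.bound_mask,
    )
    return path, wait, stable


def simulate_injection_cohort(
    n: int,
    inj: InjectionConfig,
    phys: PhotophysicsConfig,
    seed,
    duration: float = 360.0,
    frame_interval: float = 0.2,
    three_color: bool = False,
    id_prefix: str = "mol",
) -> TraceSet:
    """Simulate ``n`` molecules of a solution-injection experiment.

    Each molecule is unbound before ``injection_time`` plus an exponential
    wait; a ``fraction_stable`` subset binds irreversibly, the rest toggle
    per the post-binding scheme. Ground-truth waits, binding times and the
    stable flag are stored on each trace.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    traces = []
    for i in range(n):
        path, wait, stable = _injection_path(inj, duration, frame_interval, rng)
        if three_color:
            tr = render_three_color(path, phys, seed=rng, molecule_id=f"{id_prefix}{i:04d}")
        else:
            tr = render_two_color(path, phys, rng, molecule_id=f"{id_prefix}{i:04d}")
        tr.ground_truth.wait_time = wait
        tr.ground_truth.first_binding_time = inj.injection_time + wait
        tr.ground_truth.stable = stable
        traces.append(tr)
    return TraceSet(traces)


def simulate_two_state_cohort(
    n: int,
    scheme: KineticScheme,
    phys: PhotophysicsConfig,
    seed,
    duration: float = 120.0,
    frame_interval: float = 0.2,
    initial_state: int = 0,
    id_prefix: str = "mol",
) -> TraceSet:
    """Cohort of freely-switching (or constant, if rates are 0) traces."""
    rng = _rng(seed)
    traces = []
    for i in range(n):
        path = simulate_state_path(scheme, duration, frame_interval, rng, initial_state)
        traces.append(render_two_color(path, phys, rng, molecule_id=f"{id_prefix}{i:04d}"))
    return TraceSet(traces)


def simulate_donor_only_cohort(
    n: int,
    phys: PhotophysicsConfig,
    seed,
    duration: float = 120.0,
    frame_interval: float = 0.2,
    id_prefix: str = "donly",
) -> TraceSet:
    """Traces of molecules carrying a single donor dye (crosstalk calibration).

    The acceptor channel receives only donor leakage ``g * I`` (plus
    background and noise); the donor bleaches once.
    """
    rng = _rng(seed)
    scheme = KineticScheme(("donor_only",), np.array([0.0]), np.zeros((1, 1)))
    traces = []
    for i in range(n):
        path = simulate_state_path(scheme, duration, frame_interval, rng)
        tr = render_two_color(path, phys, rng, molecule_id=f"{id_prefix}{i:04d}")
        traces.append(tr)
    return TraceSet(traces)


def channel_noise_for_fret_sd(
    fret_sd: float, total_intensity: float, fret: float = 0.5
) -> float:
    """Per-channel Gaussian noise giving a target FRET-efficiency noise SD.

    First-order error propagation of E = A/(A+D) at FRET level ``fret``:
    sd(E) = noise_sd / I * sqrt(E^2 + (1-E)^2).
    """
    return fret_sd * total_intensity / math.sqrt(fret**2 + (1 - fret) ** 2)


# ---------------------------------------------------------------------------
# titration and solenoid


def simulate_titration(model: TitrationModel, seed) -> TitrationCurve:
    """Ensemble FRET titration under the 1:1 ligand-depletion isotherm."""
    rng = _rng(seed)
    fb = bound_fraction(model.ligand_concs, model.kd, model.sensor_conc)
    observed = model.fret_free + fb * (model.fret_bound - model.fret_free)
    if model.noise_sd > 0:
        observed = observed + rng.normal(0.0, model.noise_sd, len(fb))
    return TitrationCurve(
        ligand_concs=model.ligand_concs.copy(),
        observed_fret=observed,
        sensor_conc=model.sensor_conc,
    )


# pseudo-atom offsets per repeat, Angstrom, in the local (radial, tangential,
# axial) frame; zero-sum so the repeat centroid sits exactly on the helix
_DECOR_OFFSETS = np.array(
    [
        [3.0, 0.0, 0.0],
        [-3.0, 0.0, 0.0],
        [0.0, 3.0, 0.0],
        [0.0, -3.0, 0.0],
        [0.0, 0.0, 0.0],
    ]
)
_REPEAT_LEN = 35  # residues per repeat (consensus motif length)
# residue offsets within the motif assigned to the pseudo-atoms
_DECOR_RESIDUES = np.array([1, 8, 15, 22, 29])


def generate_ideal_solenoid(spec: SolenoidSpec, decorate: bool = True) -> CoordinateSet:
    """Ideal superhelix: repeat ``k`` reference point at
    ``(R cos(k*twist), R sin(k*twist), k*rise)``.

    With ``decorate=True`` each repeat carries five congruent pseudo-atoms
    (named CA, residues at fixed offsets within a 35-residue motif) rigidly
    placed in the local helix frame, so consecutive repeats are related by
    the exact screw motion of the solenoid.
    """
    theta = math.radians(spec.twist)
    ks = np.arange(spec.n_repeats)
    phis = ks * theta
    centers = np.column_stack(
        [spec.radius * np.cos(phis), spec.radius * np.sin(phis), ks * spec.rise]
    )
    chains, resnums, names, xyz = [], [], [], []
    annotation = []
    for k in ks:
        base = int(k) * _REPEAT_LEN
        annotation.append((base + 1, base + _REPEAT_LEN))
        c, s = math.cos(phis[k]), math.sin(phis[k])
        e_r = np.array([c, s, 0.0])
        e_t = np.array([-s, c, 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        if decorate:
            for off, res in zip(_DECOR_OFFSETS, _DECOR_RESIDUES):
                pos = centers[k] + off[0] * e_r + off[1] * e_t + off[2] * e_z
                chains.append("A")
                resnums.append(base + int(res))
                names.append("CA")
                xyz.append(pos)
        else:
            chains.append("A")
            resnums.append(base + 1)
            names.append("CA")
            xyz.append(centers[k])
    return CoordinateSet(
        chain=np.array(chains),
        resnum=np.array(resnums, dtype=int),
        atom_name=np.array(names),
        xyz=np.array(xyz),
        repeat_annotation=annotation,
    )
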