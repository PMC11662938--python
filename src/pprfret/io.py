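"""Trace containers and delimited-text I/O.

A cohort of single-molecule traces is stored as one CSV with columns
``molecule_id, frame, time_s, laser, ch_donor, ch_acceptor, ch_blue``
(``ch_blue`` empty for two-color data). Ground truth from the simulator
travels in a JSON sidecar keyed by molecule id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

LASER_GREEN = 532
LASER_BLUE = 488

_TIME_TOL = 1e-6  # s; tolerance on frame-interval uniformity


@dataclass
class TraceGroundTruth:
    """Generator-side truth attached to a simulated trace."""

    frame_states: np.ndarray | None = None  # per-frame state index
    jump_times: np.ndarray | None = None  # continuous-time jump instants, s
    jump_states: np.ndarray | None = None  # state entered at each jump
    fret_means: np.ndarray | None = None  # per-state FRET used for rendering
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None
    blue_bleach_frame: int | None = None
    wait_time: float | None = None  # exponential wait drawn after injection, s
    first_binding_time: float | None = None  # injection_time + wait, s
    stable: bool | None = None  # irreversible binder flag

    def to_jsonable(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_jsonable(cls, d: dict) -> "TraceGroundTruth":
        gt = cls()
        for k, v in d.items():
            if v is not None and k in ("frame_states", "jump_times", "jump_states", "fret_means"):
                v = np.asarray(v)
            setattr(gt, k, v)
        return gt


@dataclass
class RawTrace:
    """Per-frame multi-channel intensity record for one immobilized molecule.

    ``laser`` tags each frame with the excitation wavelength (532 or 488 nm);
    two-color traces are all-532. Times must be strictly increasing with a
    uniform frame interval (tolerance 1e-6 s).
    """

    molecule_id: str
    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    blue: np.ndarray | None = None
    laser: np.ndarray | None = None
    ground_truth: TraceGroundTruth | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.blue is not None:
            self.blue = np.asarray(self.blue, dtype=float)
        n = len(self.time_s)
        if n == 0:
            raise ValueError("empty trace")
        if len(self.donor) != n or len(self.acceptor) != n:
            raise ValueError("channel lengths disagree with time axis")
        if self.laser is None:
            self.laser = np.full(n, LASER_GREEN, dtype=int)
        else:
            self.laser = np.asarray(self.laser, dtype=int)
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if np.ptp(dt) > _TIME_TOL:
                raise ValueError("frame interval not uniform within 1e-6 s")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def frame_interval(self) -> float:
        if len(self.time_s) < 2:
            return float("nan")
        return float(np.mean(np.diff(self.time_s)))

    def slice(self, stop: int) -> "RawTrace":
        """First ``stop`` frames (e.g. up to a photobleach), ground truth kept."""
        if stop <= 0:
            raise ValueError("slice must keep at least one frame")
        return RawTrace(
            molecule_id=self.molecule_id,
            time_s=self.time_s[:stop].copy(),
            donor=self.donor[:stop].copy(),
            acceptor=self.acceptor[:stop].copy(),
            blue=self.blue[:stop].copy() if self.blue is not None else None,
            laser=self.laser[:stop].copy(),
            ground_truth=self.ground_truth,
        )


class TraceSet:
    """Ordered cohort of :class:`RawTrace` objects with table round-trip."""

    def __init__(self, traces: Sequence[RawTrace]):
        self.traces = list(traces)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[RawTrace]:
        return iter(self.traces)

    def __getitem__(self, i):
        return self.traces[i]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            n = len(tr)
            df = pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(n, dtype=int),
                    "time_s": tr.time_s,
                    "laser": tr.laser,
                    "ch_donor": tr.donor,
                    "ch_acceptor": tr.acceptor,
                    "ch_blue": tr.blue if tr.blue is not None else np.full(n, np.nan),
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TraceSet":
        df = pd.read_csv(path)
        required = {"molecule_id", "frame", "time_s", "laser", "ch_donor", "ch_acceptor"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        traces = []
        for mol, sub in df.groupby("molecule_id", sort=False):
            sub = sub.sort_values("frame")
            blue = sub["ch_blue"].to_numpy() if "ch_blue" in sub else None
            if blue is not None and np.all(np.isnan(blue)):
                blue = None
            traces.append(
                RawTrace(
                    molecule_id=str(mol),
                    time_s=sub["time_s"].to_numpy(),
                    donor=sub["ch_donor"].to_numpy(),
                    acceptor=sub["ch_acceptor"].to_numpy(),
                    blue=blue,
                    laser=sub["laser"].to_numpy(),
                )
            )
        return cls(traces)

    def write_ground_truth(self, path) -> None:
        payload = {
            tr.molecule_id: (tr.ground_truth.to_jsonable() if tr.ground_truth else None)
            for tr in self.traces
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def attach_ground_truth(self, path) -> None:
        with open(path) as fh:
            payload = json.load(fh)
        for tr in self.traces:
            gt = payload.get(tr.molecule_id)
            if gt is not None:
                tr.ground_truth = TraceGroundTruth.from_jsonable(gt)


@dataclass
class FRETTrajectory:
    """Crosstalk-corrected FRET efficiency series with truncation metadata.

    ``fret`` holds the series up to (excluding) ``truncation_frame``;
    ``imaging_lifetime`` is ``truncation_frame * frame_interval``. Frames
    with a vanishing denominator in the efficiency ratio are non-finite and
    flagged in ``nonfinite``.
    """

    molecule_id: str
    fret: np.ndarray
    frame_interval: float
    truncation_frame: int
    censored: bool = False  # True when no photobleach was observed in-record
    nonfinite: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fret = np.asarray(self.fret, dtype=float)
        if len(self.fret) != self.truncation_frame:
            raise ValueError("trajectory length must equal truncation_frame")
        if self.nonfinite is None:
            self.nonfinite = ~np.isfinite(self.fret)
        else:
            self.nonfinite = np.asarray(self.nonfinite, dtype=bool)

    def __len__(self) -> int:
        return len(self.fret)

    @property
    def imaging_lifetime(self) -> float:
        return self.truncation_frame * self.frame_interval

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.truncation_frame) * self.frame_interval


def write_fret_trajectories(trajs: Sequence[FRETTrajectory], path) -> None:
    rows = []
    for tj in trajs:
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": tj.molecule_id,
                    "frame": np.arange(len(tj)),
                    "time_s": tj.time_s,
                    "fret": tj.fret,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
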