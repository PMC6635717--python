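"""Core data types for passive wrist-stretch trials.

A trial is one motor-driven passive wrist movement from palmar flexion to
extension while a force sensor under the hand platform records the resisting
force. The protocol runs two movement speeds — a slow stretch at 5 deg/s that
stays below the stretch-reflex threshold and a fast stretch at 236 deg/s that
elicits it — each with and without the hand on the platform, so that the
instrument's own inertia can be subtracted later.

Angle convention: palmar flexion is negative, dorsal extension positive.
The movement runs from -20 deg to +30 deg (50 deg range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

from .errors import DataError, MovementIncompleteError, NoMovementError

Side = Literal["paretic", "non_paretic"]
SpeedMode = Literal["slow", "fast"]

SIDES: tuple[str, ...] = ("paretic", "non_paretic")
SPEED_MODES: tuple[str, ...] = ("slow", "fast")

#: Hard bounds on recorded wrist angle: protocol range -20..30 deg plus a
#: 5 deg allowance for overshoot/misalignment.
ANGLE_MIN_DEG = -25.0
ANGLE_MAX_DEG = 35.0

_DT_TOL_S = 1e-9


@dataclass(frozen=True)
class TraceSeries:
    """Synchronously sampled time / angle / force (optionally EMG) arrays.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, uniformly spaced and strictly increasing.
    angle : array of float
        Wrist angle in degrees (flexion negative, extension positive).
    force : array of float
        Resisting force at the platform sensor, newtons.
    emg : array of float, optional
        Surface EMG channel, millivolts.
    """

    time: np.ndarray
    angle: np.ndarray
    force: np.ndarray
    emg: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("time", "angle", "force"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.emg is not None:
            object.__setattr__(self, "emg", np.asarray(self.emg, dtype=float))
        n = self.time.size
        if n < 2:
            raise DataError("trace needs at least 2 samples")
        for name in ("angle", "force") + (("emg",) if self.emg is not None else ()):
            if getattr(self, name).size != n:
                raise DataError(f"{name} length {getattr(self, name).size} != time length {n}")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise DataError("time must be strictly increasing")
        if np.ptp(steps) > _DT_TOL_S:
            raise DataError("time must be uniformly sampled (step jitter above 1e-9 s)")
        if self.angle.min() < ANGLE_MIN_DEG or self.angle.max() > ANGLE_MAX_DEG:
            raise DataError(
                f"angle outside protocol bounds [{ANGLE_MIN_DEG}, {ANGLE_MAX_DEG}] deg"
            )

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def n(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one trial: who, which side, which speed, hand on or off."""

    subject_id: str
    side: Side
    speed_mode: SpeedMode
    hand_present: bool
    trial_index: int

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise DataError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.speed_mode not in SPEED_MODES:
            raise DataError(f"speed_mode must be one of {SPEED_MODES}, got {self.speed_mode!r}")
        if self.trial_index < 1:
            raise DataError("trial_index must be >= 1")


@dataclass(frozen=True)
class Trial:
    meta: TrialMeta
    trace: TraceSeries

    def covers_movement(self, start_angle: float = -20.0, end_angle: float = 30.0,
                        slack: float = 1.0) -> bool:
        """True if the trace spans the full protocol movement (within slack)."""
        return bool(
            self.trace.angle.min() <= start_angle + slack
            and self.trace.angle.max() >= end_angle - slack
        )


@dataclass
class TrialSet:
    """All trials recorded for one subject/side."""

    trials: list[Trial] = field(default_factory=list)

    def select(self, speed_mode: Optional[str] = None,
               hand_present: Optional[bool] = None) -> list[Trial]:
        out = []
        for t in self.trials:
            if speed_mode is not None and t.meta.speed_mode != speed_mode:
                continue
            if hand_present is not None and t.meta.hand_present != hand_present:
                continue
            out.append(t)
        return out

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ProtocolConfig:
    """Movement protocol constants.

    The slow mode stretches at 5 deg/s (below reflex threshold); the fast
    mode at 236 deg/s. Each movement travels 50 deg, from -20 deg palmar
    flexion to +30 deg extension. ``pre_hold_s`` and the per-mode post-holds
    pad the movement with stationary segments so that baselines and the
    elastic read one second after movement end are observable.
    """

    slow_speed: float = 5.0        # deg/s
    fast_speed: float = 236.0      # deg/s
    start_angle: float = -20.0     # deg
    end_angle: float = 30.0        # deg
    sample_rate: float = 1000.0    # samples/s; instrument rate is configurable
    inter_trial_interval: float = 10.0  # s, metadata only
    slow_ramp_s: float = 0.2       # cosine accel/decel ramp duration, slow mode
    fast_ramp_s: float = 0.05      # ramp duration, fast mode
    pre_hold_s: float = 1.0        # stationary hold before movement starts
    post_hold_slow_s: float = 1.2  # hold after slow movement (covers +1 s read)
    post_hold_fast_s: float = 0.4  # hold after fast movement

    def __post_init__(self) -> None:
        if self.end_angle <= self.start_angle:
            raise DataError("end_angle must exceed start_angle")
        if self.sample_rate < 100:
            raise DataError("sample_rate must be >= 100 samples/s")

    @property
    def range_deg(self) -> float:
        return self.end_angle - self.start_angle

    def nominal_speed(self, speed_mode: str) -> float:
        return self.slow_speed if speed_mode == "slow" else self.fast_speed

    def ramp_s(self, speed_mode: str) -> float:
        return self.slow_ramp_s if speed_mode == "slow" else self.fast_ramp_s

    def post_hold_s(self, speed_mode: str) -> float:
        return self.post_hold_slow_s if speed_mode == "slow" else self.post_hold_fast_s


def angular_velocity(trace: TraceSeries, smooth_samples: int = 5) -> np.ndarray:
    """Angular velocity in deg/s from centred finite differences.

    A short moving-average smoother (default 5 samples) suppresses sensor
    noise without introducing meaningful phase lag at kilohertz rates.
    """
    v = np.gradient(trace.angle, trace.time)
    k = max(1, int(smooth_samples))
    if k > 1:
        kernel = np.ones(k) / k
        v = np.convolve(v, kernel, mode="same")
    return v


def movement_onset(trace: TraceSeries, speed_threshold: float,
                   sustain_s: float = 0.02) -> float:
    """Earliest time at which angular velocity exceeds ``speed_threshold``
    and stays above it for at least ``sustain_s`` seconds.

    Raises
    ------
    NoMovementError
        If the velocity never sustains the threshold.
    """
    if speed_threshold <= 0:
        raise DataError("speed_threshold must be > 0")
    v = angular_velocity(trace)
    above = v > speed_threshold
    need = max(1, int(np.ceil(sustain_s / trace.dt)))
    if above.size >= need:
        runs = np.convolve(above.astype(float), np.ones(need), mode="valid")
        hits = np.nonzero(runs >= need - 0.5)[0]
        if hits.size:
            i0 = int(hits[0])
            # sub-sample refinement: linear interpolation of the velocity
            # crossing, so the estimate is stable under grid refinement
            if i0 > 0 and v[i0 - 1] <= speed_threshold and v[i0 - 1] < v[i0]:
                frac = (speed_threshold - v[i0 - 1]) / (v[i0] - v[i0 - 1])
                return float(trace.time[i0 - 1] + frac * trace.dt)
            return float(trace.time[i0])
    raise NoMovementError("no movement detected")


def end_of_movement(trace: TraceSeries, end_angle: float = 30.0,
                    epsilon: float = 0.5) -> float:
    """First time the wrist reaches maximal extension (within ``epsilon`` deg).

    Raises
    ------
    MovementIncompleteError
        If the angle never reaches ``end_angle - epsilon``.
    """
    target = end_angle - epsilon
    idx = np.nonzero(trace.angle >= target)[0]
    if idx.size == 0:
        raise MovementIncompleteError("movement incomplete")
    return float(trace.time[idx[0]])


#: Full-protocol trial counts per (speed_mode, hand_present) cell.
PROTOCOL_CELLS: dict[tuple[str, bool], int] = {
    ("slow", False): 2,
    ("slow", True): 5,
    ("fast", False): 2,
    ("fast", True): 10,
}


@dataclass
class ProtocolReport:
    """Outcome of protocol validation for one trial set."""

    cells: dict[tuple[str, bool], dict]
    violations: list[str]
    decomposable: bool

    def summary(self) -> str:
        lines = []
        for (mode, hand), info in self.cells.items():
            lines.append(
                f"{mode}/{'with' if hand else 'without'}-hand: "
                f"found {info['found']} (expected {info['expected']})"
            )
        lines.extend(self.violations)
        lines.append("decomposable" if self.decomposable else "NOT decomposable")
        return "\n".join(lines)


def validate_protocol(ts: TrialSet, cfg: ProtocolConfig = ProtocolConfig()) -> ProtocolReport:
    """Check a trial set against the full protocol (7 slow + 12 fast trials).

    The report lists expected vs. found counts per (speed, hand) cell and
    per-trial invariant violations. A set is *decomposable* — i.e. the
    component extraction can run — as soon as every cell holds at least one
    trial, even if the full trial counts are not met.
    """
    cells: dict[tuple[str, bool], dict] = {}
    violations: list[str] = []
    for (mode, hand), expected in PROTOCOL_CELLS.items():
        found = ts.select(mode, hand)
        cells[(mode, hand)] = {"expected": expected, "found": len(found)}
    for t in ts.trials:
        if not t.covers_movement(cfg.start_angle, cfg.end_angle):
            violations.append(
                f"trial {t.meta.speed_mode}/{'with' if t.meta.hand_present else 'without'}"
                f"-hand #{t.meta.trial_index}: movement incomplete "
                f"(angle range {t.trace.angle.min():.1f}..{t.trace.angle.max():.1f} deg)"
            )
    decomposable = all(info["found"] >= 1 for info in cells.values())
    return ProtocolReport(cells=cells, violations=violations, decomposable=decomposable)
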