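"""Decomposition of passive wrist-extension resistance into neural,
elastic and viscous components.

All reads operate on *hand-attributable* force: the without-hand trials of
the matching speed are onset-aligned, averaged, and subtracted from every
with-hand trace, removing platform inertia and the sensor offset. The three
components are then fixed-point reads of the subtracted traces:

* **EC** (elasticity component) — force one second after the end of the
  slow (5 deg/s) movement, when velocity, acceleration and any reflex have
  decayed, so only length-dependent tissue elasticity remains;
* **VC** (viscosity component) — 20 % of the first force peak of the fast
  (236 deg/s) movement, the peak being dominated by the inertial resistance
  to accelerating the hand;
* **NC** (neural component, the spasticity read) — the total
  hand-attributable force at maximal extension in the fast movement minus
  EC and VC, capturing the stretch-reflex contribution.

By construction ``nc + ec + vc`` equals the end-of-movement fast force
exactly. Components are *not* clamped at zero: a near-zero viscous read may
legitimately straddle zero on an unaffected limb.

Reads use short averaging windows (default 50 ms) rather than single
samples for noise robustness; the window width is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError
from .trace import (ProtocolConfig, TraceSeries, Trial, TrialSet,
                    end_of_movement, movement_onset, validate_protocol)

#: First-peak prominence floor: max(0.05 N, 5 % of trace range).
PEAK_PROMINENCE_FLOOR_N = 0.05
PEAK_PROMINENCE_FRACTION = 0.05

VC_FRACTION = 0.20  # viscous component = 20 % of the first fast peak


@dataclass
class Components:
    """Decomposed components (newtons) plus extraction diagnostics."""

    nc: float
    ec: float
    vc: float
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


@dataclass
class BaselineTrace:
    """Mean without-hand force on a time-since-onset grid for one speed.

    Evaluation outside the recorded span extends the edge values, so the
    baseline can be subtracted from with-hand trials of any length.
    """

    speed_mode: str
    tau: np.ndarray
    force: np.ndarray
    n_trials: int

    def at(self, tau: np.ndarray) -> np.ndarray:
        return np.interp(tau, self.tau, self.force,
                         left=self.force[0], right=self.force[-1])


def _onset(trial: Trial, cfg: ProtocolConfig) -> float:
    """Movement onset with the threshold at half the nominal mode speed,
    rounded to the sample grid so aligned trials stay sample-commensurate."""
    onset = movement_onset(trial.trace, 0.5 * cfg.nominal_speed(trial.meta.speed_mode))
    t0 = trial.trace.time[0]
    return float(t0 + round((onset - t0) / trial.trace.dt) * trial.trace.dt)


def _common_grid(spans: list[tuple[float, float]], dt: float) -> np.ndarray:
    lo = min(s[0] for s in spans)
    hi = max(s[1] for s in spans)
    i0 = int(round(lo / dt))
    i1 = int(round(hi / dt))
    return dt * np.arange(i0, i1 + 1)


def platform_baseline(ts: TrialSet, speed_mode: str,
                      cfg: ProtocolConfig = ProtocolConfig()) -> BaselineTrace:
    """Average the without-hand trials of one speed into a baseline.

    Trials are aligned at movement onset, interpolated onto a common grid
    and averaged pointwise; beyond any single trial's span its edge value is
    carried (so the baseline is defined over the union of spans).
    """
    trials = ts.select(speed_mode, hand_present=False)
    if not trials:
        raise DataError(f"baseline unavailable: no without-hand {speed_mode} trials")
    dt = trials[0].trace.dt
    aligned = []
    for tr in trials:
        onset = _onset(tr, cfg)
        tau = tr.trace.time - onset
        aligned.append((tau, tr.trace.force))
    grid = _common_grid([(a[0][0], a[0][-1]) for a in aligned], dt)
    stack = np.stack([
        np.interp(grid, tau, f, left=f[0], right=f[-1]) for tau, f in aligned
    ])
    return BaselineTrace(speed_mode=speed_mode, tau=grid,
                         force=stack.mean(axis=0), n_trials=len(trials))


def _aligned_mean_trace(ts: TrialSet, speed_mode: str, baseline: BaselineTrace,
                        cfg: ProtocolConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Onset-aligned mean of the with-hand trials of one speed, baseline
    subtracted. Returns (tau, mean angle, mean subtracted force, n)."""
    trials = ts.select(speed_mode, hand_present=True)
    if not trials:
        raise DataError(f"no with-hand {speed_mode} trials")
    dt = trials[0].trace.dt
    aligned = []
    for tr in trials:
        onset = _onset(tr, cfg)
        tau = tr.trace.time - onset
        aligned.append((tau, tr.trace.angle, tr.trace.force))
    grid = _common_grid([(a[0][0], a[0][-1]) for a in aligned], dt)
    angles = np.stack([np.interp(grid, tau, a, left=a[0], right=a[-1])
                       for tau, a, _ in aligned])
    forces = np.stack([np.interp(grid, tau, f, left=f[0], right=f[-1])
                       for tau, _, f in aligned])
    f_sub = forces.mean(axis=0) - baseline.at(grid)
    return grid, angles.mean(axis=0), f_sub, len(trials)


def _window_mean(tau: np.ndarray, values: np.ndarray, center: float,
                 window_s: float) -> float:
    half = 0.5 * window_s + 1e-9  # tolerance keeps grid-aligned edges in
    mask = (tau >= center - half) & (tau <= center + half)
    if not np.any(mask):
        raise DataError(f"no samples within the read window at tau={center:.3f} s")
    return float(values[mask].mean())


def extract_ec(ts: TrialSet, baseline: BaselineTrace,
               cfg: ProtocolConfig = ProtocolConfig(),
               window_s: float = 0.05,
               settle_s: float = 1.0) -> tuple[float, dict]:
    """Elasticity component: hand-attributable force ``settle_s`` (default
    1 s) after the end of the slow movement, averaged over ``window_s``.

    Per-trial reads are averaged across the slow with-hand trials. Trials
    that end before the read window are excluded with a warning; if all are
    excluded the component is not computable.
    """
    trials = ts.select("slow", hand_present=True)
    if not trials:
        raise DataError("EC not computable: no with-hand slow trials")
    reads, warns, t_read = [], [], None
    for tr in trials:
        onset = _onset(tr, cfg)
        t_end = end_of_movement(tr.trace, cfg.end_angle)
        center = t_end + settle_s
        if tr.trace.time[-1] < center + 0.5 * window_s:
            warns.append(
                f"slow trial #{tr.meta.trial_index} ends before the elastic read; excluded")
            continue
        tau = tr.trace.time - onset
        f_sub = tr.trace.force - baseline.at(tau)
        reads.append(_window_mean(tr.trace.time, f_sub, center, window_s))
        if t_read is None:
            t_read = center - onset
    if not reads:
        raise DataError("EC not computable: all slow trials excluded")
    return float(np.mean(reads)), {
        "t_ec_read": t_read, "n_slow_used": len(reads), "warnings": warns}


def first_peak(tau: np.ndarray, force: np.ndarray,
               t_end: Optional[float] = None,
               t_min: float = 0.0) -> tuple[float, float]:
    """First prominent local maximum of a (baseline-subtracted) fast trace
    after movement onset.

    ``tau`` is time since the velocity-threshold onset; ``t_min`` opens the
    search window (the inertial apex sits on the acceleration ramp, whose
    start precedes the half-speed onset crossing, so the caller may pass a
    small negative ``t_min``). Prominence floor:
    ``max(0.05 N, 5 % of trace range)``, evaluated on the full trace so the
    pre-onset flank counts. If no local maximum qualifies, falls back to
    the global maximum between ``t_min`` and ``t_end`` (end of movement).
    A flat trace has no peak.
    """
    if np.ptp(force) < 1e-12:
        raise DataError("no peak: flat trace")
    prominence = max(PEAK_PROMINENCE_FLOOR_N, PEAK_PROMINENCE_FRACTION * np.ptp(force))
    idx, _ = find_peaks(force, prominence=prominence)
    idx = idx[tau[idx] >= t_min]
    if idx.size:
        i = idx[0]
        return float(force[i]), float(tau[i])
    sel = tau >= t_min
    f = force[sel]
    t = tau[sel]
    upper = t_end if t_end is not None else t[-1]
    win = t <= upper
    if not np.any(win):
        raise DataError("no peak: empty search window")
    i = int(np.argmax(f[win]))
    return float(f[win][i]), float(t[win][i])


def extract_vc(p1: float) -> float:
    """Viscosity component: exactly 20 % of the first fast-movement peak."""
    if not np.isfinite(p1):
        raise DataError("p1 must be finite")
    return VC_FRACTION * p1


def extract_nc(f_end_fast: float, ec: float, vc: float) -> float:
    """Neural component: end-of-movement fast force minus EC and VC."""
    return f_end_fast - ec - vc


def decompose(ts: TrialSet, cfg: ProtocolConfig = ProtocolConfig(),
              window_s: float = 0.05, per_trial: bool = False) -> Components:
    """Run the full component extraction on one subject/side trial set.

    Stages: platform baselines (both speeds) -> EC from the slow trials ->
    first fast peak -> VC -> end-of-movement fast force -> NC. By default
    the fast with-hand trials are averaged into one aligned trace before the
    peak/end reads (noise suppression); ``per_trial=True`` instead reads
    every fast trial separately and averages the per-trial values, as a
    sensitivity variant.
    """
    report = validate_protocol(ts, cfg)
    if not report.decomposable:
        raise DataError("trial set not decomposable:\n" + report.summary())
    warns = list(report.violations)

    base_slow = platform_baseline(ts, "slow", cfg)
    base_fast = platform_baseline(ts, "fast", cfg)
    ec, ec_diag = extract_ec(ts, base_slow, cfg, window_s=window_s)
    warns.extend(ec_diag.pop("warnings"))

    if per_trial:
        p1s, tp1s, fends, tends = [], [], [], []
        for tr in ts.select("fast", hand_present=True):
            onset = _onset(tr, cfg)
            tau = tr.trace.time - onset
            f_sub = tr.trace.force - base_fast.at(tau)
            t_end = end_of_movement(tr.trace, cfg.end_angle) - onset
            try:
                p1_i, tp1_i = first_peak(tau, f_sub, t_end=t_end,
                                         t_min=-cfg.ramp_s("fast"))
            except DataError:
                p1_i, tp1_i = 0.0, float("nan")
                warns.append("fast trial: flat trace, first peak taken as 0 N")
            p1s.append(p1_i)
            tp1s.append(tp1_i)
            fends.append(_window_mean(tau, f_sub, t_end, window_s))
            tends.append(t_end)
        p1, t_p1 = float(np.mean(p1s)), float(np.mean(tp1s))
        f_end, t_end_fast = float(np.mean(fends)), float(np.mean(tends))
        n_fast = len(p1s)
    else:
        tau, angle, f_sub, n_fast = _aligned_mean_trace(ts, "fast", base_fast, cfg)
        mean_trace = TraceSeries(time=tau, angle=angle, force=f_sub)
        t_end_fast = end_of_movement(mean_trace, cfg.end_angle)
        try:
            p1, t_p1 = first_peak(tau, f_sub, t_end=t_end_fast,
                                  t_min=-cfg.ramp_s("fast"))
        except DataError:
            # a flat hand-attributable trace carries no inertial peak:
            # null viscous read rather than a hard failure
            p1, t_p1 = 0.0, float("nan")
            warns.append("fast mean trace flat: first peak taken as 0 N")
        f_end = _window_mean(tau, f_sub, t_end_fast, window_s)

    vc = extract_vc(p1)
    nc = extract_nc(f_end, ec, vc)
    diagnostics = {
        "p1": p1, "t_p1": t_p1,
        "f_end_fast": f_end, "t_end_fast": t_end_fast,
        "t_ec_read": ec_diag["t_ec_read"],
        "n_trials_used": {
            "slow_without": base_slow.n_trials, "fast_without": base_fast.n_trials,
            "slow_with": ec_diag["n_slow_used"], "fast_with": n_fast,
        },
    }
    return Components(nc=nc, ec=ec, vc=vc, diagnostics=diagnostics, warnings=warns)


def emg_relaxed(trial: Trial, cfg: ProtocolConfig = ProtocolConfig(),
                window_s: float = 0.1, k: float = 3.0) -> bool:
    """Check that the muscle stayed relaxed during the passive movement.

    True iff the moving-window RMS of the EMG channel between movement onset
    and end never exceeds ``k`` times the pre-movement baseline RMS. A
    trial with zero EMG throughout counts as relaxed. Requires at least
    0.5 s of pre-movement EMG.
    """
    if trial.trace.emg is None:
        raise DataError("trial has no EMG channel")
    trace = trial.trace
    onset = _onset(trial, cfg)
    if onset - trace.time[0] < 0.5:
        raise DataError("baseline EMG unavailable: need >= 0.5 s before movement")
    try:
        t_end = end_of_movement(trace, cfg.end_angle)
    except DataError:
        t_end = float(trace.time[-1])
    pre = trace.emg[trace.time < onset]
    base_rms = float(np.sqrt(np.mean(pre ** 2)))
    move = (trace.time >= onset) & (trace.time <= t_end)
    sq = trace.emg[move] ** 2
    w = max(1, int(round(window_s / trace.dt)))
    if sq.size < w:
        w = sq.size
    moving = np.convolve(sq, np.ones(w) / w, mode="valid")
    peak_rms = float(np.sqrt(moving.max())) if moving.size else 0.0
    if base_rms == 0.0 and peak_rms == 0.0:
        return True
    return peak_rms <= k * base_rms
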