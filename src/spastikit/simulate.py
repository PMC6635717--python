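"""Forward biomechanical simulator for passive wrist-stretch experiments.

No raw subject data accompany the study design this package implements, so
every stage is exercised against synthetic cohorts generated here. The
forward model is the minimal standard biomechanical parameterisation that is
consistent with the component semantics of the decomposition:

* an **elastic** term, length-dependent, linear-plus-exponential in the
  stretch beyond a slack angle ``theta0``:
  ``E(theta) = k_lin * s + k_exp * (exp(k_rate * s) - 1)``, ``s = max(theta - theta0, 0)``;
* a **viscous** term linear in angular velocity, ``b * theta_dot``;
* a **stretch-reflex** term: once angular velocity first exceeds the
  threshold ``v_th``, after a latency ``tau`` the reflex force ramps linearly
  over ``rise`` seconds to the amplitude ``A_N`` and then persists to the end
  of the trace (persistence is required for the end-of-movement neural read
  to capture the amplitude);
* an **inertial** term: angular acceleration (rad/s^2) times an effective
  lever arm ``r_eff`` gives the linear-equivalent acceleration at the
  sensor, multiplied by platform mass (always) and effective hand mass
  (with-hand trials);
* a constant sensor ``offset`` and i.i.d. Gaussian noise of SD ``sigma``.

All force terms are additive for a fixed trajectory, which the test suite
exploits (superposition, with-hand minus without-hand identities).

The movement trajectory is a constant-velocity plateau at the nominal
protocol speed with smooth cosine acceleration/deceleration ramps, padded by
stationary pre/post holds so that baseline segments and the elastic read one
second after movement end exist.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .trace import ProtocolConfig, TraceSeries, Trial, TrialMeta, TrialSet

#: Wrist angles (deg) at which elastography images are acquired.
SWE_ANGLES_DEG: tuple[int, ...] = (0, 10, 20, 30, 40, 50)
SWE_TRIALS = 3
SWE_IMAGES_PER_TRIAL = 5


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class MechParams:
    """Ground-truth mechanical parameters of one simulated limb.

    Units: masses kg, ``r_eff`` m, ``k_lin`` N/deg, ``k_exp`` N,
    ``k_rate`` 1/deg, ``theta0`` deg, ``b`` N.s/deg, ``v_th`` deg/s,
    ``tau`` and ``rise`` s, ``A_N`` N, ``sigma`` N, ``offset`` N.
    """

    m_eff: float = 0.15
    m_platform: float = 0.3
    r_eff: float = 0.08
    k_lin: float = 0.04
    k_exp: float = 0.04
    k_rate: float = 0.07
    theta0: float = -20.0
    b: float = 0.003
    v_th: float = 50.0
    tau: float = 0.05
    A_N: float = 4.9
    rise: float = 0.1
    sigma: float = 0.1
    offset: float = 0.3

    def validate(self) -> None:
        for name in ("m_eff", "m_platform", "r_eff", "k_lin", "k_exp", "b",
                     "A_N", "sigma", "tau", "rise"):
            if getattr(self, name) < 0:
                raise DataError(f"MechParams.{name} must be >= 0, got {getattr(self, name)}")
        if self.k_rate <= 0:
            raise DataError(f"MechParams.k_rate must be > 0, got {self.k_rate}")
        if self.v_th <= 0:
            raise DataError(f"MechParams.v_th must be > 0, got {self.v_th}")

    def elastic_force(self, angle_deg) -> np.ndarray:
        """Length-dependent elastic force E(theta) in newtons."""
        s = np.maximum(np.asarray(angle_deg, dtype=float) - self.theta0, 0.0)
        return self.k_lin * s + self.k_exp * np.expm1(self.k_rate * s)


@dataclass(frozen=True)
class SweProfileParams:
    """Shear-modulus/angle profile of one simulated muscle.

    The modulus follows ``mu(theta) = mu0 * exp(c * theta)`` (kPa, theta in
    deg of extension); ``sigma_mu`` is the between-image noise SD in kPa.
    """

    mu0: float = 10.0
    c: float = 0.01
    sigma_mu: float = 1.0

    def validate(self) -> None:
        if self.mu0 <= 0:
            raise DataError(f"SweProfileParams.mu0 must be > 0, got {self.mu0}")
        if self.c < 0:
            raise DataError(f"SweProfileParams.c must be >= 0, got {self.c}")
        if self.sigma_mu < 0:
            raise DataError(f"SweProfileParams.sigma_mu must be >= 0, got {self.sigma_mu}")

    def modulus(self, angle_deg) -> np.ndarray:
        return self.mu0 * np.exp(self.c * np.asarray(angle_deg, dtype=float))


# lower truncation bounds applied when cohort parameters are drawn
_MECH_LOWER = {
    "m_eff": 0.0, "m_platform": 0.0, "r_eff": 1e-4,
    "k_lin": 0.0, "k_exp": 0.0, "k_rate": 1e-4, "b": 0.0,
    "v_th": 1e-3, "tau": 0.0, "A_N": 0.0, "rise": 0.0,
    "sigma": 0.0, "offset": -np.inf, "theta0": -np.inf,
}
_SWE_LOWER = {"mu0": 1e-3, "c": 0.0, "sigma_mu": 0.0}


@dataclass(frozen=True)
class SideDistribution:
    """Per-side population distribution: field-wise means and SDs.

    Parameters are drawn independently per subject from normal distributions
    truncated at the physical lower bounds (no negative masses, stiffnesses
    or amplitudes at any seed).
    """

    mech_mean: MechParams
    mech_sd: dict = field(default_factory=dict)
    swe_mean: SweProfileParams = SweProfileParams()
    swe_sd: dict = field(default_factory=dict)

    def draw(self, rng: np.random.Generator) -> tuple[MechParams, SweProfileParams]:
        mech = {}
        for f in dataclasses.fields(MechParams):
            mean = getattr(self.mech_mean, f.name)
            sd = float(self.mech_sd.get(f.name, 0.0))
            val = rng.normal(mean, sd) if sd > 0 else mean
            mech[f.name] = max(val, _MECH_LOWER[f.name])
        swe = {}
        for f in dataclasses.fields(SweProfileParams):
            mean = getattr(self.swe_mean, f.name)
            sd = float(self.swe_sd.get(f.name, 0.0))
            val = rng.normal(mean, sd) if sd > 0 else mean
            swe[f.name] = max(val, _SWE_LOWER[f.name])
        return MechParams(**mech), SweProfileParams(**swe)


@dataclass(frozen=True)
class CohortParams:
    """Population-level configuration for a synthetic cohort.

    ``fma_coupling`` is the slope (points per newton) linking the paretic
    reflex amplitude to the upper-limb motor score: higher reflex amplitude
    maps to a lower score, mirroring the negative association reported for
    the instrumented neural component.
    """

    paretic: SideDistribution
    non_paretic: SideDistribution
    n_subjects: int = 15
    fma_coupling: float = 6.0
    fma_noise_sd: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise DataError("n_subjects must be >= 2")
        for side in (self.paretic, self.non_paretic):
            side.mech_mean.validate()
            side.swe_mean.validate()
            if any(v < 0 for v in side.mech_sd.values()):
                raise DataError("mech_sd entries must be >= 0")
            if any(v < 0 for v in side.swe_sd.values()):
                raise DataError("swe_sd entries must be >= 0")


def default_cohort_params(n_subjects: int = 15, seed: int = 0,
                          sigma: float = 0.1) -> CohortParams:
    """The shipped cohort configuration.

    Calibrated by simulation so that, under the full protocol and the
    default decomposition settings, cohort-mean components land near the
    published group values for hemiparetic stroke survivors
    (paretic NC/EC/VC about 4.7/3.3/0.27 N, non-paretic about 1.7/1.7/0.1 N)
    and the paretic shear-modulus profile rises with extension angle while
    exceeding the non-paretic profile at every angle.
    """
    paretic = SideDistribution(
        mech_mean=MechParams(
            m_eff=0.15, m_platform=0.3, r_eff=0.08,
            k_lin=0.04, k_exp=0.04, k_rate=0.07, theta0=-20.0,
            b=0.003, v_th=50.0, tau=0.05, A_N=4.9, rise=0.1,
            sigma=sigma, offset=0.3,
        ),
        mech_sd={"m_eff": 0.01, "k_lin": 0.015, "k_exp": 0.015, "k_rate": 0.006,
                 "b": 0.0012, "v_th": 5.0, "A_N": 3.0},
        swe_mean=SweProfileParams(mu0=12.0, c=0.020, sigma_mu=1.5),
        swe_sd={"mu0": 2.5, "c": 0.004},
    )
    non_paretic = SideDistribution(
        mech_mean=MechParams(
            m_eff=0.15, m_platform=0.3, r_eff=0.08,
            k_lin=0.024, k_exp=0.02, k_rate=0.064, theta0=-20.0,
            b=0.0008, v_th=50.0, tau=0.05, A_N=1.9, rise=0.1,
            sigma=sigma, offset=0.3,
        ),
        mech_sd={"m_eff": 0.01, "k_lin": 0.008, "k_exp": 0.008, "k_rate": 0.005,
                 "b": 0.0004, "v_th": 5.0, "A_N": 1.2},
        swe_mean=SweProfileParams(mu0=8.0, c=0.008, sigma_mu=1.0),
        swe_sd={"mu0": 1.5, "c": 0.003},
    )
    return CohortParams(paretic=paretic, non_paretic=non_paretic,
                        n_subjects=n_subjects, seed=seed)


# ---------------------------------------------------------------------------
# trajectory


@lru_cache(maxsize=32)
def _trajectory_profile(cfg: ProtocolConfig, speed_mode: str,
                        sample_rate: float) -> tuple[np.ndarray, ...]:
    """Closed-form (t, theta, omega, alpha) arrays for one protocol movement.

    Phases: pre-hold at the start angle, cosine velocity ramp of duration
    ``T_r``, constant-velocity plateau at the nominal speed, mirrored ramp
    down, post-hold at the end angle. All kinematics are evaluated
    analytically (deg, deg/s, deg/s^2).
    """
    v = cfg.nominal_speed(speed_mode)
    T_r = cfg.ramp_s(speed_mode)
    R = cfg.range_deg
    if R / v <= T_r:
        raise DataError("ramp too long for the movement range at this speed")
    t_plateau = R / v - T_r
    t_move = R / v + T_r
    total = cfg.pre_hold_s + t_move + cfg.post_hold_s(speed_mode)
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    tm = t - cfg.pre_hold_s  # time since movement start

    theta = np.full(n, cfg.start_angle)
    omega = np.zeros(n)
    alpha = np.zeros(n)

    acc = (tm >= 0) & (tm < T_r)
    ta = tm[acc]
    theta[acc] = cfg.start_angle + 0.5 * v * (ta - (T_r / np.pi) * np.sin(np.pi * ta / T_r))
    omega[acc] = 0.5 * v * (1.0 - np.cos(np.pi * ta / T_r))
    alpha[acc] = 0.5 * v * np.pi / T_r * np.sin(np.pi * ta / T_r)

    pla = (tm >= T_r) & (tm < T_r + t_plateau)
    tp = tm[pla]
    theta[pla] = cfg.start_angle + 0.5 * v * T_r + v * (tp - T_r)
    omega[pla] = v

    dec = (tm >= T_r + t_plateau) & (tm < t_move)
    td = tm[dec] - (T_r + t_plateau)
    remaining = 0.5 * v * ((T_r - td) - (T_r / np.pi) * np.sin(np.pi * td / T_r))
    theta[dec] = cfg.end_angle - remaining
    omega[dec] = 0.5 * v * (1.0 + np.cos(np.pi * td / T_r))
    alpha[dec] = -0.5 * v * np.pi / T_r * np.sin(np.pi * td / T_r)

    post = tm >= t_move
    theta[post] = cfg.end_angle

    for arr in (t, theta, omega, alpha):
        arr.setflags(write=False)
    return t, theta, omega, alpha


def make_trajectory(cfg: ProtocolConfig, speed_mode: str,
                    sample_rate: Optional[float] = None) -> TraceSeries:
    """Protocol movement trajectory as an (angle-only) trace; force is zero."""
    rate = cfg.sample_rate if sample_rate is None else sample_rate
    if rate < 100:
        raise DataError("sample_rate must be >= 100 samples/s")
    t, theta, _, _ = _trajectory_profile(cfg, speed_mode, rate)
    return TraceSeries(time=t, angle=theta, force=np.zeros_like(t))


# ---------------------------------------------------------------------------
# force synthesis


def reflex_force(t: np.ndarray, omega: np.ndarray, p: MechParams) -> np.ndarray:
    """Stretch-reflex force N(t): threshold trigger, latency, linear rise,
    persistence until the end of the trace. Zero if the velocity never
    exceeds ``v_th``."""
    above = omega > p.v_th
    if not np.any(above):
        return np.zeros_like(t)
    t0 = t[np.argmax(above)] + p.tau
    if p.rise > 0:
        ramp = np.clip((t - t0) / p.rise, 0.0, 1.0)
    else:
        ramp = (t >= t0).astype(float)
    return p.A_N * ramp


def _deterministic_force(p: MechParams, hand_present: bool, t, theta, omega, alpha
                         ) -> np.ndarray:
    a_lin = np.deg2rad(alpha) * p.r_eff  # m/s^2 at the sensor
    f = p.m_platform * a_lin + p.offset
    if hand_present:
        f = f + p.m_eff * a_lin + p.elastic_force(theta) + p.b * omega
        f = f + reflex_force(t, omega, p)
    return f


def simulate_trial(p: MechParams, meta: TrialMeta,
                   cfg: ProtocolConfig = ProtocolConfig(),
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   include_emg: bool = False,
                   emg_noise_mv: float = 0.01) -> Trial:
    """Simulate one passive-stretch trial.

    Without the hand the sensor sees only platform inertia plus offset and
    noise; with the hand the elastic, viscous and reflex terms are added.
    ``seed`` (or an explicit ``rng``) fixes the noise stream.
    """
    p.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    t, theta, omega, alpha = _trajectory_profile(cfg, meta.speed_mode, cfg.sample_rate)
    f = _deterministic_force(p, meta.hand_present, t, theta, omega, alpha)
    if p.sigma > 0:
        f = f + rng.normal(0.0, p.sigma, size=t.size)
    else:
        f = f.copy()
    emg = None
    if include_emg:
        emg = rng.normal(0.0, emg_noise_mv, size=t.size)
    return Trial(meta=meta, trace=TraceSeries(time=t, angle=theta.copy(), force=f, emg=emg))


# ---------------------------------------------------------------------------
# subjects and cohorts


@dataclass
class SubjectRecord:
    """One synthetic subject: both sides' trials, elastography, clinical data
    and the ground-truth parameters behind them."""

    subject_id: str
    trials: dict  # side -> TrialSet
    swe: pd.DataFrame  # subject_id, side, angle_deg, trial, image, vs_mps, mu_kpa
    fma: int
    mas: str
    params: dict  # side -> (MechParams, SweProfileParams)
    sex: str = "M"
    affected_side: str = "L"


def _simulate_swe_table(subject_id: str, side: str, sp: SweProfileParams,
                        rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for angle in SWE_ANGLES_DEG:
        mu_true = float(sp.modulus(angle))
        for trial in range(1, SWE_TRIALS + 1):
            noise = rng.normal(0.0, sp.sigma_mu, size=SWE_IMAGES_PER_TRIAL) \
                if sp.sigma_mu > 0 else np.zeros(SWE_IMAGES_PER_TRIAL)
            mu = np.maximum(mu_true + noise, 0.0)
            vs = np.sqrt(mu)  # m/s when mu in kPa and rho = 1000 kg/m^3
            for image in range(1, SWE_IMAGES_PER_TRIAL + 1):
                rows.append((subject_id, side, angle, trial, image,
                             float(vs[image - 1]), float(mu[image - 1])))
    return pd.DataFrame(rows, columns=["subject_id", "side", "angle_deg",
                                       "trial", "image", "vs_mps", "mu_kpa"])


def _trial_plan() -> list[tuple[str, bool, int]]:
    """Full protocol per side: 7 slow (2 without + 5 with hand), then 12
    fast (2 without + 10 with hand)."""
    plan = []
    idx = 0
    for hand in (False, False, True, True, True, True, True):
        idx += 1
        plan.append(("slow", hand, idx))
    idx = 0
    for hand in (False, False) + (True,) * 10:
        idx += 1
        plan.append(("fast", hand, idx))
    return plan


def simulate_subject(subject_id: str,
                     params: dict,
                     cfg: ProtocolConfig = ProtocolConfig(),
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     fma_coupling: float = 6.0,
                     fma_noise_sd: float = 12.0,
                     include_emg: bool = False) -> SubjectRecord:
    """Simulate a full study visit for one subject.

    ``params`` maps each side to a ``(MechParams, SweProfileParams)`` pair.
    Per side the full protocol trial set is produced, plus the elastography
    table (6 angles x 3 trials x 5 images). The motor score is
    ``clip(round(66 - fma_coupling * A_N_paretic + noise), 0, 66)``; the
    spasticity grade is drawn from {1, 1+, 2} with only weak coupling to the
    reflex amplitude, so null grade correlations remain attainable.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trials: dict[str, TrialSet] = {}
    swe_tables = []
    for side in ("paretic", "non_paretic"):
        mech, swe_p = params[side]
        ts = TrialSet()
        for mode, hand, idx in _trial_plan():
            meta = TrialMeta(subject_id=subject_id, side=side, speed_mode=mode,
                             hand_present=hand, trial_index=idx)
            ts.trials.append(simulate_trial(mech, meta, cfg, rng=rng,
                                            include_emg=include_emg))
        trials[side] = ts
        swe_tables.append(_simulate_swe_table(subject_id, side, swe_p, rng))
    a_n = params["paretic"][0].A_N
    fma = int(np.clip(round(66.0 - fma_coupling * a_n + rng.normal(0.0, fma_noise_sd)),
                      0, 66))
    grade_score = a_n + rng.normal(0.0, 4.0)
    mas = "1" if grade_score < 3.5 else ("1+" if grade_score < 6.5 else "2")
    return SubjectRecord(subject_id=subject_id, trials=trials,
                         swe=pd.concat(swe_tables, ignore_index=True),
                         fma=fma, mas=mas, params=params,
                         affected_side=str(rng.choice(["L", "R"])))


def simulate_cohort(cp: CohortParams, seed: Optional[int] = None,
                    cfg: ProtocolConfig = ProtocolConfig(),
                    include_emg: bool = False) -> list[SubjectRecord]:
    """Simulate a cohort of subjects with independently drawn parameters.

    Fully reproducible from ``seed`` (defaults to ``cp.seed``). Roughly 80 %
    of subjects are flagged male in the fixture metadata (12/3 at n = 15,
    matching the study demographics).
    """
    cp.validate()
    rng = np.random.default_rng(cp.seed if seed is None else seed)
    n_male = int(round(0.8 * cp.n_subjects))
    records = []
    for i in range(cp.n_subjects):
        params = {
            "paretic": cp.paretic.draw(rng),
            "non_paretic": cp.non_paretic.draw(rng),
        }
        rec = simulate_subject(f"S{i + 1:02d}", params, cfg, rng=rng,
                               fma_coupling=cp.fma_coupling,
                               fma_noise_sd=cp.fma_noise_sd,
                               include_emg=include_emg)
        rec.sex = "M" if i < n_male else "F"
        records.append(rec)
    return records
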