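"""Component extraction against closed-form oracles."""

import dataclasses

import numpy as np
import pytest

from spastikit import (DataError, MechParams, SweProfileParams, TraceSeries,
                       Trial, TrialMeta, TrialSet, decompose, emg_relaxed,
                       extract_ec, extract_vc, first_peak, platform_baseline,
                       simulate_subject, simulate_trial)
from spastikit.simulate import _trajectory_profile
from tests.conftest import QUIET_PARAMS, ZERO_PARAMS


def _subject_ts(p, cfg, seed=0, swe=SweProfileParams()):
    params = {s: (p, swe) for s in ("paretic", "non_paretic")}
    return simulate_subject("t", params, cfg, seed=seed).trials["paretic"]


class TestBaseline:
    def test_identical_trials_mean_is_idempotent(self, cfg):
        ts = _subject_ts(QUIET_PARAMS, cfg)
        base = platform_baseline(ts, "fast", cfg)
        single = ts.select("fast", hand_present=False)[0]
        # both without-hand trials are noiseless and identical
        np.testing.assert_allclose(
            base.at(single.trace.time - 1.0 - 0.025),
            base.at(single.trace.time - 1.0 - 0.025))
        assert base.n_trials == 2

    def test_platform_only_oracle(self, cfg):
        """sigma = 0 platform trace equals m_platform * a_lin + offset."""
        p = QUIET_PARAMS
        ts = _subject_ts(p, cfg)
        base = platform_baseline(ts, "fast", cfg)
        t, theta, omega, alpha = _trajectory_profile(cfg, "fast", cfg.sample_rate)
        oracle = p.m_platform * np.deg2rad(alpha) * p.r_eff + p.offset
        # align the oracle to the baseline's onset-relative clock
        trial = ts.select("fast", hand_present=False)[0]
        from spastikit import movement_onset
        onset = movement_onset(trial.trace, 118.0)
        np.testing.assert_allclose(base.at(t - onset), oracle, atol=1e-9)

    def test_missing_cell_raises(self, cfg):
        ts = _subject_ts(QUIET_PARAMS, cfg)
        stripped = TrialSet([t for t in ts.trials
                             if not (t.meta.speed_mode == "fast"
                                     and not t.meta.hand_present)])
        with pytest.raises(DataError, match="baseline unavailable"):
            platform_baseline(stripped, "fast", cfg)


class TestElasticRead:
    def test_null_simulation_gives_zero(self, cfg):
        comp = decompose(_subject_ts(ZERO_PARAMS, cfg), cfg)
        assert comp.ec == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_elastic_law(self, cfg):
        """sigma = 0: the read 1 s after the slow movement ends must equal
        E(30 deg) for the 50 deg stretch, evaluated analytically."""
        p = dataclasses.replace(ZERO_PARAMS, k_lin=0.1, k_exp=0.05,
                                k_rate=0.08, theta0=-20.0)
        comp = decompose(_subject_ts(p, cfg), cfg)
        e30 = 0.1 * 50.0 + 0.05 * np.expm1(0.08 * 50.0)
        assert comp.ec == pytest.approx(e30, abs=1e-9)

    def test_linear_in_elastic_coefficients(self, cfg):
        p = dataclasses.replace(QUIET_PARAMS, sigma=0.0)
        doubled = dataclasses.replace(p, k_lin=2 * p.k_lin, k_exp=2 * p.k_exp)
        ec1 = decompose(_subject_ts(p, cfg), cfg).ec
        ec2 = decompose(_subject_ts(doubled, cfg), cfg).ec
        assert ec2 == pytest.approx(2 * ec1, abs=1e-9)

    def test_short_trace_excluded_with_warning(self, cfg):
        ts = _subject_ts(QUIET_PARAMS, cfg)
        base = platform_baseline(ts, "slow", cfg)
        truncated = []
        for tr in ts.trials:
            if tr.meta.speed_mode == "slow" and tr.meta.hand_present:
                # movement completes at 11.2 s; the elastic read needs ~12.1 s
                n = int(11.5 * cfg.sample_rate)
                tr = Trial(meta=tr.meta, trace=TraceSeries(
                    time=tr.trace.time[:n], angle=tr.trace.angle[:n],
                    force=tr.trace.force[:n]))
            truncated.append(tr)
        with pytest.raises(DataError, match="EC not computable"):
            extract_ec(TrialSet(truncated), base, cfg)


class TestFirstPeakAndVc:
    def test_constructed_unimodal_bump(self):
        t = np.linspace(-0.5, 1.5, 2001)
        f = 3.0 * np.exp(-((t - 0.4) / 0.1) ** 2)
        p1, t_p1 = first_peak(t, f)
        assert p1 == pytest.approx(3.0, abs=1e-3)
        assert t_p1 == pytest.approx(0.4, abs=1e-3)

    def test_flat_trace_has_no_peak(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(DataError, match="no peak"):
            first_peak(t, np.full_like(t, 2.0))

    def test_monotone_rise_falls_back_to_window_max(self):
        t = np.linspace(-0.2, 1.0, 1201)
        f = np.clip(t, 0, None) * 5.0
        p1, t_p1 = first_peak(t, f, t_end=0.5)
        assert p1 == pytest.approx(2.5, abs=1e-2)

    @pytest.mark.parametrize("p1,expected", [(10.0, 2.0), (0.0, 0.0),
                                             (1.35, 0.27)])
    def test_vc_is_twenty_percent_of_peak(self, p1, expected):
        assert extract_vc(p1) == pytest.approx(expected, abs=1e-12)

    def test_vc_rejects_non_finite_peak(self):
        with pytest.raises(DataError):
            extract_vc(float("nan"))

    def test_peak_on_simulated_fast_trace_is_inertial(self, cfg):
        """With sigma = 0 the first peak falls on the acceleration ramp,
        where the inertia of the hand dominates."""
        comp = decompose(_subject_ts(QUIET_PARAMS, cfg), cfg)
        ramp = cfg.fast_ramp_s
        assert -ramp <= comp.diagnostics["t_p1"] <= 2 * ramp
        # oracle: maximum of the hand-attributable force over the ramp
        p = QUIET_PARAMS
        t, theta, omega, alpha = _trajectory_profile(cfg, "fast", cfg.sample_rate)
        hand = (p.m_eff * np.deg2rad(alpha) * p.r_eff
                + p.elastic_force(theta) + p.b * omega)
        ramp_mask = (t >= cfg.pre_hold_s) & (t <= cfg.pre_hold_s + ramp)
        assert comp.diagnostics["p1"] == pytest.approx(hand[ramp_mask].max(),
                                                       rel=1e-6)


class TestDecompose:
    def test_additivity_identity(self, small_cohort, cfg):
        for rec in small_cohort[:2]:
            for ts in rec.trials.values():
                comp = decompose(ts, cfg)
                assert comp.nc + comp.ec + comp.vc == pytest.approx(
                    comp.diagnostics["f_end_fast"], abs=1e-9)

    def test_nc_recovers_reflex_amplitude_up_to_end_residual(self, cfg):
        """sigma = 0, A_N = 5 N: NC - A_N equals the oracle end-residual
        (inertial + viscous + elastic window terms minus VC)."""
        p = dataclasses.replace(QUIET_PARAMS, A_N=5.0)
        comp = decompose(_subject_ts(p, cfg), cfg)
        t, theta, omega, alpha = _trajectory_profile(cfg, "fast", cfg.sample_rate)
        i_end = int(np.argmax(theta >= cfg.end_angle - 0.5))
        win = np.abs(t - t[i_end]) <= 0.025 + 1e-9
        resid = float(np.mean(
            p.m_eff * np.deg2rad(alpha[win]) * p.r_eff
            + p.elastic_force(theta[win]) + p.b * omega[win]
        )) - p.elastic_force(30.0) - comp.vc
        assert comp.nc - 5.0 == pytest.approx(resid, abs=1e-6)

    def test_nc_additive_shift_equivariance(self, cfg):
        """With EC and VC held fixed, a constant added to every with-hand
        fast force sample shifts the end-of-movement read — and hence the
        neural read — by exactly that constant."""
        from spastikit import extract_nc
        ts = _subject_ts(QUIET_PARAMS, cfg)
        shift = 2.5
        shifted = TrialSet([
            Trial(meta=tr.meta, trace=TraceSeries(
                time=tr.trace.time, angle=tr.trace.angle,
                force=tr.trace.force + shift))
            if tr.meta.speed_mode == "fast" and tr.meta.hand_present else tr
            for tr in ts.trials
        ])
        c0 = decompose(ts, cfg)
        c1 = decompose(shifted, cfg)
        f0 = c0.diagnostics["f_end_fast"]
        f1 = c1.diagnostics["f_end_fast"]
        assert f1 - f0 == pytest.approx(shift, abs=1e-9)
        assert extract_nc(f1, c0.ec, c0.vc) - extract_nc(f0, c0.ec, c0.vc) \
            == pytest.approx(shift, abs=1e-12)
        assert c1.ec == pytest.approx(c0.ec, abs=1e-12)

    def test_removing_the_hand_zeroes_all_components(self, cfg):
        """With-hand trials physically identical to platform-only runs must
        decompose to components that vanish within sensor noise."""
        p = dataclasses.replace(ZERO_PARAMS, m_platform=0.3, offset=0.3,
                                sigma=0.1)
        ts = _subject_ts(p, cfg, seed=21)
        comp = decompose(ts, cfg)
        assert abs(comp.ec) < 0.15
        assert abs(comp.vc) < 0.15
        assert abs(comp.nc) < 0.3

    def test_nc_monotone_in_reflex_amplitude(self, cfg):
        ncs = []
        for a_n in (0.0, 4.0):
            p = dataclasses.replace(QUIET_PARAMS, A_N=a_n)
            ncs.append(decompose(_subject_ts(p, cfg), cfg).nc)
        assert ncs[1] > ncs[0]

    def test_per_trial_variant_agrees_when_noiseless(self, cfg):
        ts = _subject_ts(QUIET_PARAMS, cfg)
        c_mean = decompose(ts, cfg, per_trial=False)
        c_per = decompose(ts, cfg, per_trial=True)
        assert c_per.nc == pytest.approx(c_mean.nc, abs=1e-6)
        assert c_per.vc == pytest.approx(c_mean.vc, abs=1e-6)

    def test_not_decomposable_raises(self, cfg):
        ts = _subject_ts(QUIET_PARAMS, cfg)
        stripped = TrialSet([t for t in ts.trials
                             if t.meta.speed_mode != "fast"])
        with pytest.raises(DataError, match="not decomposable"):
            decompose(stripped, cfg)


class TestEmgRelaxed:
    def _trial(self, cfg, emg):
        from spastikit import make_trajectory
        traj = make_trajectory(cfg, "slow")
        trace = TraceSeries(time=traj.time, angle=traj.angle,
                            force=traj.force, emg=emg)
        return Trial(meta=TrialMeta("s", "paretic", "slow", True, 1),
                     trace=trace)

    def _n(self, cfg):
        from spastikit import make_trajectory
        return make_trajectory(cfg, "slow").n

    def test_gaussian_noise_is_relaxed(self, cfg):
        rng = np.random.default_rng(4)
        trial = self._trial(cfg, rng.normal(0, 0.01, self._n(cfg)))
        assert emg_relaxed(trial, cfg)

    def test_mid_movement_burst_is_flagged(self, cfg):
        rng = np.random.default_rng(4)
        emg = rng.normal(0, 0.01, self._n(cfg))
        emg[5000:5300] += 0.1 * np.sin(np.linspace(0, 60, 300))  # 10x burst
        trial = self._trial(cfg, emg)
        assert not emg_relaxed(trial, cfg)

    def test_all_zero_emg_counts_as_relaxed(self, cfg):
        assert emg_relaxed(self._trial(cfg, np.zeros(self._n(cfg))), cfg)

    def test_missing_pre_movement_baseline_raises(self, cfg):
        from spastikit import make_trajectory
        traj = make_trajectory(cfg, "slow")
        keep = traj.time >= 0.9  # only 0.1 s before movement
        trace = TraceSeries(time=traj.time[keep], angle=traj.angle[keep],
                            force=traj.force[keep],
                            emg=np.zeros(int(keep.sum())))
        trial = Trial(meta=TrialMeta("s", "paretic", "slow", True, 1),
                      trace=trace)
        with pytest.raises(DataError, match="baseline EMG unavailable"):
            emg_relaxed(trial, cfg)
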