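# Methods

## The measurement model

Spasticity presents as hyper-resistance to passive joint rotation with
neural (hyperactive stretch reflex) and non-neural (tissue elasticity and
viscosity) contributors. The package implements the fixed-point reading
scheme used with motorised wrist-extension instruments: the wrist travels
from −20° palmar flexion to +30° extension (50° range) at 5°/s (slow) and
236°/s (fast), each speed run both with and without the hand on the
platform. The full protocol is 7 slow trials (2 without / 5 with hand) and
12 fast trials (2 without / 10 with hand).

All component reads operate on *hand-attributable* force: the without-hand
trials of the matching speed are aligned at movement onset, averaged, and
subtracted from the with-hand traces. The instrument's own inertia and the
sensor offset cancel in this subtraction. This is a package design choice —
the protocol records platform-only runs without prescribing their use, and
subtraction is the only reading that makes the components hand-specific.

The three reads are:

- **EC** — mean hand-attributable force in a 50 ms window centred 1 s
  after the end of the slow movement. One second into the hold, velocity
  and acceleration are zero and no reflex was elicited (5°/s is far below
  reflex threshold), so the read isolates length-dependent elasticity at
  30° extension.
- **VC** — 0.20 × P1, with P1 the first prominent local maximum of the
  fast hand-attributable trace. The fast movement's acceleration ramp
  makes the inertia of the hand the dominant early force, and the 20 %
  rule converts that peak into a viscosity estimate.
- **NC** — mean hand-attributable force in a 50 ms window centred at the
  time the wrist first reaches 29.5° (end of movement, tolerance ε = 0.5°)
  in the fast trials, minus EC and VC. Since the reflex persists once
  elicited, this residual captures the reflex amplitude.

NC + EC + VC equals the end-of-movement fast read exactly, by
construction. Components are never clamped: a slightly negative viscous
read on an unaffected limb is an expected consequence of the peak
heuristic plus noise, and clamping would bias group means.

### First-peak definition

"First peak" needs an operational definition. We use the first local
maximum, *after the movement starts*, whose topographic prominence is at
least max(0.05 N, 5 % of the trace range); if none qualifies, the global
maximum between onset and end of movement is used. Two numerical details
matter:

- prominence is evaluated on the full trace, so the flat pre-movement
  flank counts toward the early peak's prominence (slicing the trace at
  onset first would truncate that flank and spuriously reject the peak);
- the search window opens at −(fast ramp duration) relative to the
  detected onset, because onset is detected at the half-nominal-speed
  crossing, which sits mid-ramp — *after* the inertial apex for
  low-viscosity limbs.

### Onset, end, and alignment

Onset is the earliest time the centred-difference angular velocity
(5-sample moving-average smoothed) exceeds a threshold — half the nominal
mode speed in the decomposition — and stays above it for ≥ 20 ms, refined
to sub-sample precision by linear interpolation of the crossing. For trace
alignment the onset is rounded back to the sample grid so that all trials
of a subject stay sample-commensurate and window reads average identical
sample sets. End of movement is the first sample with angle ≥ 30° − ε.

Reads use 50 ms averaging windows rather than single samples (configurable
via `window_ms`); with 1 kHz sampling and the trial counts above, the
standard error of a read under 0.1 N sensor noise is a few millinewtons.
By default the fast with-hand trials are averaged into one aligned trace
before the peak/end reads; a `per_trial` flag instead reads each trial and
averages the results, as a sensitivity variant.

## Elastography

The scanner reports shear-wave speed Vs per image; μ = ρ·Vs² with
ρ = 1000 kg/m³, so μ in kPa is numerically Vs² (m/s). The package consumes
per-image values only (image formation and ROI placement are
acquisition-side), aggregates 3 trials × 5 images per angle into per-angle
mean ± sample SD (n − 1 denominator, since the profiles feed inferential
statistics), and contrasts profiles between sides and across the 0°–50°
sweep.

## The simulator

The generator exists because no raw data of this kind are public; it
produces protocol-conformant cohorts with known ground truth so that the
decomposition can be validated by parameter recovery. Its force model is
the minimal standard parameterisation consistent with the component
semantics:

F(t) = m·a_lin(t) + E(θ) + b·θ̇ + N(t) + offset + noise

- **Trajectory**: constant-velocity plateau at the nominal speed with
  cosine acceleration ramps (0.2 s slow, 0.05 s fast), a 1 s stationary
  pre-hold and a post-hold (1.2 s slow — covering the +1 s elastic read —
  0.4 s fast). Kinematics are evaluated in closed form.
- **Inertia**: angular acceleration (rad/s²) × effective lever arm
  r_eff = 0.08 m gives the linear-equivalent acceleration at the sensor;
  the platform mass (0.3 kg) loads every trial, the effective hand mass
  m_eff only with-hand trials. Outputs stay in newtons.
- **Elasticity**: E(θ) = k_lin·s + k_exp·(e^{k_rate·s} − 1) on the stretch
  s = max(θ − θ₀, 0), θ₀ = −20° (slack at the start position). Linear +
  exponential is the standard passive muscle-tendon form.
- **Viscosity**: b·θ̇, b in N·s/deg.
- **Reflex**: when θ̇ first exceeds v_th = 50°/s, after a 50 ms latency
  the reflex force ramps linearly over 100 ms to A_N and persists to the
  end of the trace. Persistence is required for the end-of-movement neural
  read to capture A_N; 50°/s guarantees silence in slow mode.
- **Noise**: i.i.d. Gaussian per sample (default SD 0.1 N) — the simplest
  falsifiable choice; no coloured noise.

All force terms are additive for a fixed trajectory, giving exact
superposition and with-hand-minus-platform identities that the tests
exploit as oracles.

Elastography profiles follow μ(θ) = μ₀·e^{c·θ} with between-image Gaussian
noise on μ (floored at zero before taking Vs = √μ). Clinical fixtures: the
upper-limb motor score is clip(round(66 − 6·A_N,paretic + ε), 0, 66) with
ε ~ N(0, 12) — a moderate negative association between reflex amplitude
and motor function, not a deterministic link; the ordinal spasticity grade
is drawn from {1, 1+, 2} only weakly coupled to A_N, so null grade
correlations remain attainable (as observed clinically, grade scales
correlate poorly with instrumented measures).

### Cohort calibration

`default_cohort_params()` draws each parameter per subject from a normal
distribution truncated (clipped) at its physical lower bound. The side
means were calibrated by simulation so that cohort-mean components land
near the group values reported for hemiparetic stroke survivors
(paretic NC/EC/VC ≈ 4.7/3.3/0.3 N, non-paretic ≈ 1.7/1.7/0.0 N):

| parameter | paretic | non-paretic | note |
|---|---|---|---|
| m_eff (kg) | 0.15 ± 0.01 | 0.15 ± 0.01 | early fast peak ≈ m_eff·a ≈ 1.6 N |
| k_lin (N/deg) | 0.040 ± 0.015 | 0.024 ± 0.008 | E(30°) ≈ 3.3 vs 1.7 N |
| k_exp (N) | 0.040 ± 0.015 | 0.020 ± 0.008 | |
| k_rate (1/deg) | 0.070 ± 0.006 | 0.064 ± 0.005 | |
| b (N·s/deg) | 0.0030 ± 0.0012 | 0.0008 ± 0.0004 | drives the VC contrast |
| A_N (N) | 4.9 ± 3.0 | 1.9 ± 1.2 | drives the NC contrast |
| μ₀ (kPa) | 12.0 ± 2.5 | 8.0 ± 1.5 | side offset at rest |
| c (1/deg) | 0.020 ± 0.004 | 0.008 ± 0.003 | paretic profile rises ~2.7× over 50° |

Two calibration facts are worth knowing when interpreting recovery
numbers. First, the end-of-movement read occurs during the deceleration
ramp, so NC carries a known negative inertial residual (≈ −0.8 N at these
settings) on *both* sides; the reflex amplitudes above are therefore set
slightly over the target component means, and the recovery experiment
reports this residual rather than hiding it. Second, the 20 %-of-peak
viscous heuristic retains the (side-shared) hand-inertia term, so the
non-paretic VC sits near +0.1 N rather than exactly zero; the paretic
minus non-paretic contrast, which is the scientifically relevant quantity,
is unaffected.

## Statistics

Two-sided tests, α = 0.05. Paired t-tests compare components between
sides. The stiffness profiles enter a two-way fully within-subject ANOVA
(side × angle), each effect tested against its own subject-by-effect
stratum; sphericity is uncorrected by default (a Greenhouse–Geisser flag
is provided; with only two side levels the correction matters only for the
angle terms). Within each side, a one-way repeated-measures ANOVA across
the six angles is followed by all 15 pairwise paired t-tests with
Bonferroni adjustment (raw p × 15, capped at 1) — the all-pairs family
matches how angle contrasts are conventionally reported for this design.
Pearson correlations relate components to the modulus (both the 30° value
and the across-angle mean, labelled separately, since both conventions
appear in practice) and to the motor score. The ordinal spasticity grade
(coded 0, 1, 1+, 2, 3, 4 → 0…5; "1+" between 1 and 2 is a declared
convention) uses Spearman's rho with average ranks; for n ≤ 8 the p-value
is the exact two-sided permutation probability, otherwise the t
approximation with n − 2 df. Degenerate inputs are handled explicitly:
identical pairs give t = 0 / p = 1, zero-variance differences with nonzero
mean report the limiting p = 0 with a note, zero-variance correlations
raise a named error, and incomplete repeated-measures crossings raise an
error listing the missing cells.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline recovers the parameters of
*its own* forward model: exact elastic recovery without noise, sub-0.2 N
recovery at realistic noise, rank-faithful neural reads, and reproduction
of the qualitative group structure (paretic > non-paretic for all three
components and for the modulus at every angle; a within-side angle effect
on the paretic side) in ≥ 90 % of 100 cohort seeds. They do not show that
the component reads are unbiased for real muscle, whose elasticity is
history-dependent (thixotropy), whose reflex is velocity- and
length-modulated rather than a step-and-hold, and whose sensor noise is
not white. The simulator also draws mechanical and elastographic
parameters independently, so cross-instrument correlations are null by
construction; observed correlations in real cohorts are a property of the
population, not of the analysis.

## Problem sizes and determinism

Default problem sizes: 15 subjects × 2 sides × 19 trials at 1 kHz for the
study pipeline (seconds per cohort), 20 subjects for recovery experiments,
100 seed replicates for the qualitative-replication checks. Every random
draw flows from a single `numpy` generator seeded from the user-supplied
seed; identical configuration and seed reproduce byte-identical JSON
reports (reports deliberately carry no timestamps, only the package
version, seed and a config hash).

## Known limitations

- No inertia component is reported; the inertial end-residual is folded
  into NC (documented above) as the component set is limited to NC/EC/VC.
- The continuous-time model is never fitted to traces by optimisation; the
  decomposition is deliberately the fixed-point reading scheme.
- EMG handling is limited to a relaxation check (moving RMS during the
  movement ≤ 3 × pre-movement baseline RMS over 0.1 s windows); no
  activation modelling.
- MAS generation is a coarse three-grade fixture; it exists to let the
  grade-correlation battery run, not to model clinical grading.
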