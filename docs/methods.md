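# Methods

This note records the scientific and numerical choices behind wristdyn: the
models, their assumptions, the defaults and why, what the synthetic data
does and does not emulate, and the known limitations.

## Impedance model of wrist–forearm rotations

The wrist and forearm are modelled as a frictionless universal joint: all
three rotation axes intersect at one point (the small distal offset of the
radial–ulnar axis relative to the flexion–extension axis is neglected, as is
standard for wrist dynamics). Coordinates are q = (α, β, γ) with α the
forearm pronation–supination (most proximal), β wrist flexion–extension and
γ radial–ulnar deviation; the rotation sequence is proximal→distal,
R = Ry(α)·Rz(β)·Rx(γ), with the lab y axis along the neutral forearm.
Placing α most proximal is forced by the structure of the inertia matrix:
the forearm's longitudinal moment IAy enters only the αα entry.

Under this convention the hand's body-frame angular velocity is

    ωx = γ̇ + α̇ sin β
    ωy = β̇ sin γ + α̇ cos β cos γ
    ωz = β̇ cos γ − α̇ cos β sin γ

and every dynamic term derives from the kinetic energy
T = ½(IHx ωx² + IHy ωy² + IHz ωz² + IAy α̇²). This single source of truth
has two consequences we exploit:

* **Coriolis terms are computed twice.** The authoritative path builds
  C(q, q̇) q̇ from Christoffel symbols using the analytic gradient of M(q);
  a second, independently coded closed-form expansion of the same
  Euler–Lagrange equations is kept behind `method="table"`. The test suite
  asserts mutual agreement and agreement with a finite-difference oracle on
  1000 random draws. (This caught a real index-transposition bug during
  development.)
* **Gravity is a potential gradient.** The hand is a point mass m at
  distance l from the wrist along the hand's long axis;
  U(q) = −m·g·l·(ĝ·d̂(q)) with ĝ the unit gravity-pull direction (default
  along lab +z) and d̂ the hand direction. The gravity torque is ∇U,
  available in closed form for the default direction and validated against
  a central-difference gradient to 1e−6 relative error.

Passive damping and stiffness are constant 3×3 matrices; stiffness is
symmetric (enforced at construction), matching the measured symmetry of
passive wrist–forearm stiffness. The stiffness torque is K(q − q_rest) with
q_rest defaulting to the neutral posture (0, 0, 0).

**Integration.** Forward dynamics uses the classical fixed-step 4th-order
Runge–Kutta scheme, default dt = 1 ms. At physiological stiffness-to-inertia
ratios (ω ≈ √(K/M) ≈ 30 rad/s) this leaves energy drift below 1e−6 relative
over 5 s, which the suite checks; adaptive stepping is deliberately out of
scope. The inertia matrix is guarded by a condition-number limit (1e12) and
the integrator raises on non-finite states. Accelerations missing from an
input trajectory are filled by second-order central differences (one-sided
at the ends).

## Torque decomposition and coupling statistics

Main torques use only the diagonal entries of M, B, K; interaction torques
only the off-diagonal entries. The centripetal/Coriolis vector exists only
through inter-DOF velocity coupling, so it is classified as interaction by
default; `coriolis_as` can route it to `main` or `excluded` instead.
Gravity cannot be split and is reported separately, excluded from the
ratios but included among the per-source magnitudes Mj.

The magnitude metric carries the cross term 2·Mα·Mγ·sin β because the
pronation–supination and deviation axes become colinear at β = ±90°; the
integrand equals (Mα + Mγ sin β)² + Mβ² + Mγ² cos²β and is therefore
non-negative. The same metric is used for the numerator and denominator of
R and Rj for consistency. Quadrature is the trapezoidal rule on the sample
grid with no resampling; tests require agreement with a brute-force
quadrature within 0.1 % on ≥ 1000-sample fixtures.

## Parameter identification

**Anthropometrics.** Hand inertia uses shipped segment-parameter regression
coefficients (mass fractions of body mass, a centre-of-mass fraction of
hand length, per-axis radius-of-gyration fractions, from the standard
cadaver/gamma-scan tables). Transverse moments are transported to the wrist
joint via the parallel-axis theorem; the longitudinal moment is not. An
explicit `hand_com_fraction` on the profile overrides the table.

**Stiffness regression.** τ = K q (+ τ0) is fitted by least squares with K
parameterized by its six free entries, so symmetry holds exactly by
construction rather than by averaging K̂ij and K̂ji after the fact (the
9-parameter averaged variant is available for comparison). The optional
per-axis constant offset τ0 implements the session "axis offset". Rank
deficiency raises an error naming the unexcited parameter directions (right
singular vectors of the design). The fit is unbiased: over 500 seeded noise
replicates the mean estimate is within 0.5 % of truth.

**Damping.** B = c·K with c chosen so the flexion–extension diagonal is
exactly 0.03 Nms/rad, the upper end of the measured passive FE damping
range (0.02–0.03 Nms/rad).

**Iterative passive extraction.** The regression repeats over quasi-static
rounds until the relative Frobenius change of K̂ between rounds falls below
1e−3 (our choice; the convergence criterion is presented only visually to
the clinician in the target workflow), capped at 12 rounds to mirror the
protocol's set count. Non-convergence is flagged, not raised.

## EMG pipeline

Filtering is a 2nd-order Butterworth band-pass (10–2000 Hz) followed by a
2nd-order IIR notch at 50 Hz with quality factor 30. A "first-order notch"
is not a realizable standard design, so the minimal standard biquad notch is
used; this is a documented deviation. Filters are applied forward–backward
(zero phase) by default to avoid phase distortion in the features; a causal
mode exists for streaming parity. When the sampling rate cannot support the
upper band edge it is clipped to 0.45·fs with a warning; the synthetic
default fs is 10 kHz, consistent with the 2000 Hz edge. fs is always read
from the data, never assumed.

Windowing: non-overlapping 0.25 s short-term windows and 2 s mid-term
windows with 1 s step, trailing partial windows dropped. Because fatigue
evolves slowly, the classifier consumes mid-term windows only; short-term
segmentation is exposed but unused by default.

Per window the PSD is a Hann-tapered one-sided periodogram with
Parseval-consistent normalization (mean removed first); Welch averaging is
unnecessary at these window lengths but the periodogram call accepts a
taper argument. Features: MNF = Σfj·Pj/ΣPj, MNP = ΣPj/M, and MDF as the
first bin whose cumulative power reaches half the total. MNF/MDF are
undefined (raised) for an all-zero spectrum; MNP is 0 there.

## Fatigue classification

The classifier is a support-vector machine on (MNF, MNP), z-scored with
training-set statistics only. Default kernel RBF with C = 1 and
gamma = 1/(n_features·var); no hyperparameter values are prescribed by the
target workflow, so the sklearn defaults are kept and a grid search is left
to the caller. Splits are subject-wise (grouped) to prevent windows of one
subject appearing on both sides. Feature ranking uses information gain with
quantile binning (10 bins; discrete features are binned by value) — a
documented stand-in for the unspecified "uncertainty algorithm" of the
original workflow. Persisted models store scaler statistics and
support-vector data as JSON; the reloaded decision function evaluates the
kernel directly and matches the fitted pipeline to rounding.

The fatigue→torque mapping is the least constrained part of the system: the
minimal faithful reading is a binary decrement τ_fatigue = δ·τ_active,max
when fatigue is detected, with δ configurable (default 0.3, no prescribed
value exists) and an optional margin-proportional mode. The resultant
torque subtracts the decrement on the active movement axis only (exercises
are single-axis by joint locking) and floors the axis magnitude at zero.

## Protocol and scoring

Stage 1 runs the iterative passive identification; stage 2 measures peak
voluntary torque and achieved RoM against a resistive robot and is skipped
when the peak torque is below a minimal legible threshold (default
0.05 Nm, configurable — no prescribed value exists); stage 3 executes the
continuous exercises, per day extracting RoM and peak active torque,
estimating the fatigue fraction from the day's EMG windows, and logging the
fatigue-adjusted resultant torque. When a day carries its own quasi-static
probe the passive stiffness is re-fitted so the report's passive-torque
series tracks recovery.

RPF = current RoM / theoretical RoM × 10, capped at 10. The displayed score
truncates toward zero at one decimal (5.77… displays as 5.7); the raw value
is preserved. The theoretical pronation–supination range is 90° — the value
consistent with the scoring's worked examples — although anatomical
pronation + supination spans 180°; flexion–extension is 130° (70 + 60) and
ulnar–radial 50° (30 + 20). All three are user-overridable.

## Synthetic data

The sEMG generator shapes white Gaussian noise with the two-corner band
spectrum P(f) ∝ f²·fh² / ((f² + fl²)(f² + fh²)²), corners fl = 60 Hz,
fh = 120 Hz, placing MNF in the physiological 60–120 Hz band. Fatigue
multiplies both corners by (1 − shift) with shift = 0.35 and scales the RMS
amplitude by 0.8. The amplitude factor is deliberately below 1: the
synthetic dataset must reproduce the qualitative ordering that both MNF and
MNP are higher in the nonfatigue state, and since MNP here is proportional
to total signal power, an amplitude rise under fatigue would invert the MNP
ordering. Between-subject variability is log-normal (σ = 0.1) on corners
and amplitude. The default dataset simulates 57 subjects with 4 mid-term
windows per state each, processed through the real filtering/windowing/PSD
pipeline.

What this emulates: the spectral compression and power change of fatigued
sEMG, between-subject spectral variability, mains interference (optional
50 Hz component), and the grouped structure needed for leakage-free splits.
What it does not: motor-unit firing statistics, nonstationarity within a
window, motion artifacts, electrode placement effects, or real
inter-subject label noise. Classifier accuracies on this data (routinely
near 100 % on held-out subjects at the default separation) therefore bound
the pipeline's correctness, not its clinical performance; published
recordings-based accuracies (~90 %) are not reproducible without the
original recordings.

Protocol streams interpolate a subject's RoM ceiling, torque ceiling and
passive-stiffness scale linearly across exercise days (defaults 54→84°,
0.5→0.8 Nm, stiffness ×0.4), with a rest day and within-day fresh→fatigued
EMG, giving monotone ground truth for protocol-level tests.

Problem sizes used by the test suite and acceptance script — 1000 random
draws for the dynamics oracles, 5 s simulations at dt = 1 ms, 1500-sample
quadrature fixtures, 200-point regressions with 500 replicates, 57-subject
datasets over 20 seeds — were chosen as the smallest sizes at which the
checked tolerances are meaningful.

## Known limitations

* No musculotendon or activation dynamics: "active torque" is an abstract
  input; the robot appears only through the torque it injects.
* Batch identification only; no online/recursive estimation.
* The dynamics model assumes constant B and K, though both are known to
  vary with posture and muscle state.
* The fatigue-torque mapping is a modelling choice, not a measured
  relation; δ should be treated as a tunable clinical parameter.
* Display truncation of RPF is an interface convention; downstream
  computation should use the raw score.
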