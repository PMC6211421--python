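# Methods

`gaitdyn` models and classifies six-degree-of-freedom (6-DOF) knee gait
kinematics to separate anterior-cruciate-ligament-deficient (ACL-D) from
intact (ACL-I) knees. This note documents the model, the synthetic cohort
generator, the numerical choices, and what the tests do and do not show.

## Pipeline

1. **Input.** Per subject: six tibiofemoral channels — varus–valgus (VV),
   internal–external rotation (IE), flexion–extension (FE) in degrees;
   anterior–posterior (AP), proximal–distal (PD), medial–lateral (ML)
   translations in cm — sampled at 60 Hz for 15 s during 3 km/h treadmill
   walking (gait cycle ≈ 1.08 s).
2. **Phase-space reconstruction.** Each of the four discriminative reference
   channels (IE, FE, AP, PD — the ones whose range of motion differs
   significantly between groups) is delay-embedded with dimension d = 3 and
   lag τ = 1: rows `(V_j, V_{j+τ}, V_{j+2τ})`. The Euclidean distance (ED) of
   each embedded point from the origin gives one scalar feature series per
   channel; stacking yields the feature trajectory
   `x(t) = [ED_IE, ED_FE, ED_AP, ED_PD]^T`.
3. **Normalization.** Each feature column is affinely mapped to [−1, 1] using
   the min/max over *training* subjects only; the frozen map is applied to
   test data, clipping at ±1.2 (the lattice edge) with a logged warning.
4. **Deterministic learning.** The unknown gait dynamics `x' = φ(x)` are
   identified by the dynamical RBF observer
   `x̂' = −a(x̂ − x) + Ŵ^T S(x)`,
   `Ŵ_i' = −γ S(x) x̃_i − σ γ Ŵ_i`,
   with Gaussian activations `s_i(z) = exp(−‖z − μ_i‖²/η²)` on a regular
   lattice, Ŵ(0) = 0. Along the periodic (persistently exciting) gait orbit
   the locally active weights converge; the constant pattern is the time
   average `W̄ = mean Ŵ(t)` over the trailing 25% of the training horizon.
5. **Classification.** One frozen estimator per training subject:
   `χ̄' = −b(χ̄ − x) + W̄^T S(x)` driven by the test trajectory. The
   synchronization error `χ̃ = χ̄ − x` is summarized by the gait-cycle-windowed
   average L1 norm (window Tc = 1.08 s, 65 samples at 60 Hz), time-averaged
   and state-averaged into one score per estimator. The test subject receives
   the group label of the smallest-score (best-synchronizing) estimator; ties
   break to the lowest index and are logged.
6. **Evaluation.** Stratified single-split twofold CV (9 ACL-D + 14 ACL-I
   training subjects for an 18/28 cohort; the extra subject of an odd group
   trains) and leave-one-subject-out (LOSO) CV. The normalizer and all
   estimators are refit per fold from training data only. ACL-D is the
   positive class. Metrics are computed in exact rational arithmetic.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| d, τ | 3, 1 | embedding dimension and lag |
| lattice | 17 nodes/dim on [−1.2, 1.2]⁴, N = 83521 | RBF centers |
| η | grid spacing (0.15 at defaults) | Gaussian width |
| a | 0.5 /s | observer gain |
| γ | 1.5 | learning rate (diagonal Γ) |
| σ | 1e−3 | leakage (σ-modification) |
| b | 30 /s | estimator gain magnitude |
| Tc | 1.08 s | error-norm window = gait cycle |
| epochs | 12 | passes over the 15 s trajectory |

Two deliberate sign/magnitude choices:

- **Estimator gain b.** The error system `χ̄' = −B(χ̄ − x) + …` is stable only
  for positive diagonal B; the gain is implemented as magnitude 30. A negative
  value would make every estimator diverge.
- **Leakage σ.** σ-modification is a small robustness term. A large σ (e.g.
  10 with γ = 1.5, i.e. a 15 /s weight-forgetting rate) erases the weight
  memory within a fraction of one gait cycle, so the converged `W̄^T S(x)`
  becomes a strongly attenuated, phase-lagged echo of the dynamics: in our
  experiments the matched estimator then fails to beat a zero-weight
  estimator, and the limit-cycle identification error stays ≈ 100%. The
  default is σ = 1e−3, small relative to the persistent-excitation level;
  σ is config-exposed.

## Numerical integration

Training uses an explicit first-order scheme with zero-order-hold input and
**symplectic (semi-implicit) ordering**: the observer state is advanced with
the old weights, then the weight update uses the *new* tracking error. The
tracking-error/weight pair is an oscillatory system (frequency ≈
√(γ·ΣS²)); plain simultaneous Euler amplifies it (observed divergence for
wide RBF overlap), while the symplectic ordering keeps it neutrally stable
for dt·√(γ·ΣS²) < 2 — comfortably satisfied at all defaults. An RK4 option
exists (`TrainingConfig(integrator="rk4")`). Halving dt changes the learned
field along a test orbit by < 1% (consistency test). Estimator runs use the
same explicit scheme (b·dt < 2 enforced; 0.5 at defaults) evaluated as a
linear filter.

Activations below 1e−8 are truncated to exactly zero, and weights are stored
only on the nodes the training orbit ever excites (all others provably stay
zero under zero initialization).

## Desk-scale (reduced) configuration

The full 83521-node lattice is supported but unnecessary for the synthetic
experiments. Tests and the acceptance script use a reduced configuration
chosen from convergence diagnostics (weight drift, tracking-error decay,
matched-vs-zero-weight error ratio):

- lattice 7 nodes/dim (N = 2401), width = 2 × grid spacing (0.8). The wider
  relative width raises the persistent-excitation level of the orbit, which
  the coarser grid would otherwise lose;
- γ = 4.5 over 10 epochs. Only the product (learning rate × training time)
  governs the averaged weight dynamics; this schedule reproduces the
  convergence diagnostics of γ = 1.5 over 30 epochs at a third of the cost.
- LOSO memoizes trained patterns by (subject, normalizer parameters):
  removing a non-extremal subject leaves the fold's min/max normalizer — and
  hence each retrained pattern — bit-identical, so the cache is pure
  memoization with fold hygiene intact.

The toy limit-cycle identification (2-D circular orbit with analytic
derivative) uses a 21-node/dim 2-D lattice, width 1.5 × spacing, γ = 15,
σ = 1e−4, 300 one-cycle epochs at 240 Hz; it reaches ≈ 1–2% relative RMSE
against the analytic field, and near-zero predictions far from the orbit
(locality).

## Synthetic cohort generator

No public recording of the study cohort exists. The generator emulates the
*documented* properties: per-channel unit-amplitude cycle templates (fixed
truncated Fourier series; the FE template has the classic early-stance bump,
terminal-stance extension minimum and dominant swing-flexion peak in the
second half of the cycle), scaled per subject by a range-of-motion (ROM) draw
`R_c ~ Normal(mean, SD)` truncated at zero, using the published per-group ROM
means/SDs (ACL-D walks with reduced FE/IE/PD but increased AP excursion).
Per-cycle multiplicative amplitude jitter (CV 3%, applied to the deviation
from the heel-strike value so cycles join continuously), additive measurement
noise (0.25° rotations / 0.05 cm translations — optical capture scale), an
optional random initial phase, and a fixed 1.08 s cycle at 60 Hz for 15 s
complete the model. One root seed spawns an independent stream per subject.

What it does **not** emulate: within-subject cycle *shape* variability,
group differences in waveform shape (group signal enters only through ROM
distributions), pathological timing asymmetries, treadmill-speed effects, or
soft-tissue artifacts. Consequently, passing the synthetic end-to-end tests
shows the machinery discriminates amplitude-borne dynamics differences; it
does not certify performance on clinical recordings.

Noise and amplitude jitter inflate the per-trial max−min ROM slightly
(jitter maxima ≈ +5%, noise tails ≈ +2×3σ_noise) — identically in both
groups, so effect sizes are nearly unchanged. Parameter-recovery tests
therefore run with noise and jitter off.

## Known limitations

- The single-nearest-pattern decision is a 1-NN rule. With group differences
  carried only by the ROM distributions, its accuracy ceiling on a 46-subject
  cohort is the 1-NN Bayes-type limit (empirically ≈ 0.78 mean LOSO accuracy
  for an oracle 1-NN on the true ROM vectors, varying strongly across cohort
  draws); a group-level rule such as LDA reaches ≈ 0.85 but is out of scope.
- ROM here is per-trial max − min; per-cycle averaging (which the published
  table may have used) is not implemented.
- Embedding-dimension/lag selection beyond fixed values and first-zero
  autocorrelation is out of scope, as are musculoskeletal simulation,
  kinetics, and streaming detection.
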