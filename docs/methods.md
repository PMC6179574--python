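# Methods

`gazedecode` is a fully synthetic re-creation of a combined visual working
memory (VWM) / mental imagery MEG experiment in which delay-period "memory
decoding" can be produced entirely by small, stimulus-specific eye
movements.  This note documents the generative model, the decoding and
inference procedures, the numerical choices, and what the simulations can
and cannot show about real recordings.

## The simulated experiment

Each trial of the main task presents a rotation cue (417 ms) and a blank
(417 ms), then a grating for 217 ms at one of three orientations (15°, 75°,
135°, clockwise from vertical), followed by a long blank delay (8.017 s by
default, shortenable) and a probe.  The cued rotation is 0° (pure VWM), 60°,
120° or 180°, clockwise or counterclockwise, to be performed mentally at
30°/s; each of the 8 design cells contributes 3 trials per block and 6
blocks give 144 trials per subject.  The probe's orientation jitter is
controlled by the adaptive staircase described below.  A separate functional
localizer presents six orientations (15°–165° in 30° steps) for 250 ms each,
120 trials per orientation, with attention held at fixation.

All orientations live on the half-open interval [0°, 180°), and every
circular computation doubles the angle first (period 180° → 360°); the
doubling is centralized in `gazedecode.angles`.

## Generative model

Per subject (all quantities deterministic functions of `(seed, subject)`
through `numpy.random.SeedSequence`):

* **Neural orientation code.** A fixed sensor mapping `A` (`n_sensors x 2`,
  orthonormal columns) carries the doubled-angle code
  `pattern(α) = A [cos 2α, sin 2α]`, so patterns are smooth, 180°-periodic
  and unit-norm.  A transient response (gain `neural_transient_gain`,
  default 1, active 0–0.5 s) follows the presented grating; an optional
  sustained response (`neural_sustained_gain`, default 0) follows the
  current *mental* orientation through the delay, so it rotates away from
  the stimulus in the rotation conditions.  The localizer contains only the
  transient response through the *same* `A`, which is what lets
  localizer-trained decoders generalize to genuine neural signal.
* **Gaze confound.** From 0.3 s after stimulus onset (a free parameter; the
  data only constrain decodability to rise around 0.5 s) the gaze ramps
  within 0.2 s from fixation to a point at distance `a` (degrees visual
  angle) along the remembered grating's orientation axis, where `a` is a
  subject trait drawn log-uniformly from 0.05°–1.5° (mean ≈ 0.43°,
  bracketing the reported range of such drifts) unless fixed via
  `gaze_amplitude_deg`.  Which end of the axis is also a subject trait.
  During mental rotation the gaze tracks the rotating orientation at 30°/s
  but saturates ±60° from the starting orientation
  (`gaze_saturation_deg`), and holds until the probe.  Measured gaze =
  latent trajectory + white tracker noise (0.2°).
* **Eyeball-dipole artifact.** The latent gaze leaks into the sensors as
  `eye_dipole_gain · G [g_x, g_y]`, with `G` a frontal-weighted random
  mixing (unit-norm columns; loadings concentrated on low sensor indices to
  stand in for frontal channels).  The default gain of 2 makes one degree
  of gaze displacement comparable to the evoked response — ocular artifacts
  in MEG are large.  By default `G` is orthogonalized against both `A` and
  `Σ₀⁻¹A` (`Σ₀` the true noise covariance), so noise-weighted filters built
  from localizer patterns are blind to the artifact subspace by
  construction; `dipole_orthogonal=False` allows overlapping subspaces for
  realism studies.  Residual, subject-idiosyncratic leakage has a random
  phase per subject and cancels at the group level.
* **Noise.** Multivariate Gaussian, spatial covariance
  `Σ₀ = σ² ρ^|i−j|` (`noise_spatial_corr`, default 0.3), white in time.
  Temporal whiteness is a deliberate simplification: it makes adjacent
  time points independent at the noise level, which if anything makes
  sustained decoding *harder* to fake, and it keeps the generator fast.

Scaled defaults (64 sensors for 275, 120 Hz for 1200 Hz) keep a subject's
dataset in tens of megabytes; the delay can be shortened for quick runs.
Analysis-scale runs in this repository use a 3 s delay — long enough for a
complete 60° rotation plus a saturated hold — and decimate decoding time
axes to ~30 Hz, which is lossless relative to the 100 ms smoothing.  Catch
trials are not generated.

### What the generator does not emulate

Saccade dynamics and the oculomotor main sequence, pupil signals, real
sensor geometry and head anatomy, non-stationary or temporally correlated
sensor noise, ocular ICA residue structure, and any non-orientation task
factor.  Passing tests therefore show that the *analysis chain* behaves as
specified under the stated confound mechanism — not that real datasets are,
or are not, confounded.

## Decoding analyses

**Probabilistic classifier.**  Class-conditional Gaussians with shared
covariance and flat prior: `P(k|x) = softmax(w_k'x + w_k0)` with
`w_k = S⁻¹m_k`, `w_k0 = −½ m_k'S⁻¹m_k`.  `S` is the unweighted mean of the
per-class sample covariances (denominator `n_k − 1`), shrunk as
`(1−λ)S + λνI` with `ν` the mean diagonal; λ = 0.05 for MEG features and
0.01 for the two gaze features.  Posteriors use log-sum-exp stabilization.
Cross-validation is stratified 8-fold with seeded assignment; training
always pools all task conditions, and condition-specific results restrict
only the *test* trials.  Classifiers are trained at every time point and
applied at every time point (temporal generalization); data are smoothed
with a 100 ms centered moving average first and baseline-corrected on
−200–0 ms (relative to stimulus onset for MEG, cue onset for gaze).  With
λ = 0 the posteriors are invariant to any shared invertible affine feature
map; shrinkage breaks this exact invariance by fixing the `νI` target in
the observed feature basis.

**Inverted encoding model.**  24 von Mises channels,
`C_j(φ) = exp(κ(cos(2φ − 2μ_j) − 1))` with κ = 5, peak-normalized to 1.
Channel patterns are estimated by least squares of the sensor data on the
design matrix; with `k` distinct training orientations only a
`k`-dimensional subspace of channel space is identifiable, and the
minimum-norm solution is used (six localizer orientations make the design
rank-6 by construction, which is expected).  The inversion uses per-channel
unit-gain noise-weighted spatial filters `w_j = Σ⁻¹p_j / (p_j'Σ⁻¹p_j)`,
with `Σ` the shrinkage-regularized residual covariance — this reduces to
pattern projection when `Σ ∝ I` and demonstrably lowers decoding error
under correlated noise.  Channel activities are collapsed to an orientation
estimate by the activation-weighted circular mean of the channel centers;
trials with a vanishing resultant are flagged NaN and excluded (with a
count) from summaries.  This inversion carries a systematic interpolation
ripple of roughly 1–2° between channel centers when the underlying sensor
code is low-dimensional; the ripple is phase-locked to the true orientation
and cancels in the trial-averaged statistic.

Decoding quality across trials is summarized by
`z = N⁻¹ Σ_k exp(i(2θ_k − 2φ_k))`, `ρ = |z|cos(arg z) = Re z` — the V-test
statistic: +1 when decoded and true orientations agree, −1 at 90° offset
(counterphase after doubling), 0 at 45° offset or no relation.

**Cluster permutation inference.**  One-sample t maps against chance
(1/3 for three-class posteriors, 1/6 for six, 0 for ρ); clusters of
adjacent supra-threshold points (two-tailed p < 0.05 pointwise;
4-connectivity in 2-D, chains in 1-D), masses = summed t, sign-separated.
The null sign-flips each subject's map about chance with probability ½
(10,000 permutations by default; analysis-scale runs here use 500–1,000 and
state the coarser p resolution); p values carry the +1 correction so p = 0
cannot occur.  Each sign family is tested at α = 0.05; the two families are
not jointly corrected, and the type-I simulation calibrates each family at
its nominal level.

The pipeline's "delay decoding significant" flag means: significant
positive clusters cover more than half of the test samples between 1 s
(after the transient response and smoothing margin) and probe onset, on the
profile averaged over the 0.5–1.5 s training window (0.09–0.12 s for the
localizer-trained decoder).

**Spatial patterns.**  Per class, the difference between the class-mean
evoked field and the grand mean, averaged over a time window.  For balanced
classes these sum to zero across classes, so the cross-class summary is the
root-mean-square pattern rather than the mean.

## Staircase

Probe jitter starts at 15°, +1° after an error, −0.5488° after two
consecutive correct responses (a weighted up/down rule), floored at 0.1°
(the rule itself has no floor; the floor only prevents non-physical
negative jitter under near-perfect observers).  In the pair approximation
the equilibrium percent correct solves `0.5488 p² = 1 − p²`, i.e.
`p = √(1/1.5488) ≈ 0.8036`; long simulations with a cumulative-Gaussian
observer confirm the ~80% asymptote independently of the starting value.
Asymptotic estimates discard the first half of trials as burn-in.

## Seeds and determinism

Every stochastic component takes a seed; the pipeline spawns per-stage
child seeds (generator / fold assignment / permutations) from one master
seed via `SeedSequence`, and identical configurations produce byte-identical
output bundles.  Subject-level structures (mixing matrices, axis end, drift
amplitude) depend only on `(generator seed, subject index)`, so task and
localizer data of one subject share the same neural code.

## Known limitations

* The dipole–filter orthogonality is exact only against the *true* noise
  covariance; estimated, shrunk covariances leave a small idiosyncratic
  leak per subject (random phase, group-cancelling).
* ρ on small condition subsets is noisy (sd ≈ (2n)^(−1/2) per matrix cell);
  condition-wise ρ values from few trials should be averaged over windows.
* The two-sided cluster test at 0.05 per sign family implies up to ~0.10
  family-wise across both signs.
* The staircase model assumes responses conditionally independent given the
  jitter; sequential dependencies in real observers shift the equilibrium
  slightly.
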