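# Methods

## Scope and intent

`gainfield` implements two rate-based models of eye-position gain
modulation of retinotopic visual responses, plus the analyses used to
quantify their behavior.  Everything is generated internally — there is no
external data; the models *are* the object of study.

## Hardwired model

Each of the 1491 visual neurons is assigned a unique preferred retinal
location α (integer degrees in [−10, 10]) and preferred eye position β
(integer degrees in [−35, 35]).  Its internal activation is the **sum** of
two Gaussians — retinal distance (width σ) and eye-position distance
(width ρ) — each peaking at h_max, and its rate is a sigmoid of that
activation.  Defaults: σ = 6°, ρ = 20°, h_max = 0.485, sigmoid slope
φ = 1.9, threshold θ = 0.99.  The additive combination followed by a
saturating nonlinearity is what produces *approximately multiplicative*
gain modulation: near threshold the sigmoid is locally exponential, so an
additive shift in activation scales the output curve.

Units: all angles in degrees; activations and rates dimensionless; rates in
(0, 1).  Neurons are identified by their (α, β) pair everywhere — storage
order (β slowest, α fastest) is an arbitrary recorded convention.

### Eye sweeps and linearity

A neuron's gain field is measured by clamping the stimulus at its preferred
retinal location and sweeping the eye across all 71 integer positions.
Linearity is the coefficient of determination of an OLS line fit with
intercept, R² = 1 − SSE/SST ∈ [0, 1].  Numerical conventions:

- SST < 1e−12 (flat curve) → R² := 0, flagged degenerate.
- R² < 1e−15 is reported as exactly 0: at double precision this is a
  zero-slope fit, which is what symmetric (peaked) gain fields produce.
- The "significant activity" gate (max rate ≥ 0.1 and range ≥ 0.05,
  both configurable) marks near-silent curves.  It is applied when
  summarizing *trained* networks, whose outputs can be silent; every
  hardwired neuron clears it, so hardwired population statistics are
  unaffected.  The R² value itself is always computed.

Increasing ρ flattens the eye-position Gaussian over the tested range, so
the population's R² distribution shifts upward; the package's ρ-sweep
(2.5°–25°) reproduces this monotone trend in the population median and in
the 0.2-wide histogram bins (half-open, top bin closed).

### Multiplicativity test

For a family of retinal-sweep curves at fixations {−35, −12, 0, 12, 35}°
(or {−20, −12, 0, 12, 20}° for trained networks), each non-reference curve
r_e is fitted by a single scale constant applied to the straight-ahead
curve r₀: c_e = ⟨r₀, r_e⟩/⟨r₀, r₀⟩, the least-squares optimum.  The
statistic is the worst relative residual max_e ‖c_e r₀ − r_e‖/‖r_e‖, with a
default pass tolerance of 0.05.  The residual is exactly 0 for families
built as scalar multiples (conservation check in the tests).  Note that the
models are only *approximately* multiplicative: the sigmoid's saturation
and its output floor both break exact scaling, and the strongest-gain
fixations show relative residuals near 0.1 for edge neurons.  The 5 %
default is therefore a strict criterion; callers can pass their own
tolerance.

### Profile classification

A deliberately coarse, fully configurable rule used only for summarizing
trained populations: *unresponsive* if the activity gate fails; *monotonic*
if the curve's maximum lies within 2 grid steps of a boundary and its total
variation ≤ 1.1× its range (essentially single-sloped); *peaked* if the
maximum is ≥ 5° interior and the rate falls by ≥ 20 % of the range on both
sides; otherwise monotonic (the larger-R² reading of an ambiguous curve).

## Self-organizing model

- **Input layer**: 71 eye-position units (preferred values at 1° spacing on
  [−35, 35]) and 21 retinal units (on [−10, 10]); Gaussian activations
  (ρ default 15°, σ = 6°, h_max = 2) through a sigmoid with φ = 4.5,
  θ = 0.  One θ serves both the input and output sigmoids.  Input rates
  are instantaneous functions of the current condition (no input dynamics).
- **Output layer**: 100 neurons, τ = 100 ms leaky integrators advanced by
  Forward–Euler with dt = τ/10 = 10 ms.
- **Competition**: the rate sigmoid's argument is h_i − p_π − θ, where p_π
  is the π-th percentile (π = 90) of the current activations, recomputed
  every step.  Percentile definition: nearest rank, the ⌈πN/100⌉-th
  smallest value; with N = 100 distinct activations exactly 10 outputs
  exceed rate 0.5.  The training logs confirm 10 % mean instantaneous
  sparseness.
- **Connectivity**: each output receives ⌊ϕ/100 · 92⌋ = 9 afferents
  (ϕ = 10 %), drawn without replacement; floor keeps the count
  deterministic.  The symbol ϕ is connectivity only; the sigmoid slope is
  always φ.
- **Learning**: Δw_ij = dt · ϱ · v_i · v_j on existing synapses
  (ϱ = 0.05/s), then each output row is renormalized to unit Euclidean
  norm.  Rows are also normalized once at initialization (weights uniform
  on [0, 1] on the mask), so the unit-norm invariant holds from t = 0.
  Non-negative rates keep all weights non-negative (Dale-consistent).
  A zero learning rate short-circuits the update entirely so the stored
  weights are returned bit-for-bit unchanged.

### Training schedule

An epoch presents the stimulus at each of the 21 retinal locations
(sequential order by default; shuffling available).  Within a period the
eyes visit 15 uniform random integer positions in [−35, 35]°, fixating
300 ms at each, joined by 14 constant-velocity 400°/s saccades; the eye
position interpolates linearly during saccades and learning stays on
(a switch restricts learning to fixations; the default was chosen because
the model makes no assumption about stimulus–saccade timing).  Each period
is entered through an *un-counted* transition saccade from the previous
period's final eye position, preserving the 15/14 accounting.  Saccade
step counts are rounded up to whole dt steps with the endpoint exact.

The protocol's nominal arithmetic — 21 locations × 2 s × 10 epochs =
420 s — is exposed as `nominal_training_duration`.  The stated 2 s
presentation per location is incompatible with 15 × 300 ms fixations
(4.5 s of fixation alone), so two schedule modes exist:
`fixation_defined` (default; ≈ 5.3 s per period including saccade time)
and `nominal_2s` (fixation durations rescaled so each period lasts 2 s).
The default keeps the fixation statistics, which drive learning, at their
stated values.

### Testing trained networks

Trained responses are evaluated at the integrator's fixed point
h* = W·v_in(x, y) for each condition on the full 21 × 71 grid, with
competition applied across the population per condition.  Each output is
characterized at its *best retinal location* (the retinal index of its
response-surface maximum).  With the default parameters the trained
population spans near-zero to ≈ 0.99 eye-sweep R², and widening ρ from
2.5° to 25° shifts the dominant profile class from peaked/unresponsive
toward monotonic — the same width effect as in the hardwired model.

### Randomness and determinism

One global seed expands through `numpy.random.SeedSequence.spawn` into
three named streams — connectivity, initial weights, fixation targets — so
changing one consumer never perturbs the others.  Identical seed + config
give bitwise-identical weight trajectories; the stochastic analyses in the
test suite use seeds {1, 2, 3} and majority/pooled criteria.

## Numerical choices

- Exponent arguments clamped to ±700 before `exp`: rates saturate to 0/1
  within floating tolerance instead of overflowing; immaterial in the
  default parameter range.
- Non-finite activations or weights abort with the offending event logged.
- OLS fits delegate to `scipy.stats.linregress`; the test suite checks it
  against an independent normal-equations implementation at 1e−10.

## Problem sizes

The hardwired analyses are closed-form and run in seconds (1491 neurons ×
71 eye positions; six-ρ sweep well under 10 s).  A full training run
(≈ 110,000 Euler steps) takes tens of seconds; multi-seed analyses use
3 seeds per condition, which is enough for the majority-vote and pooled
range criteria they feed.

## What the generator does and does not emulate

Training stimuli are noiseless, single, point-like stimuli with uniform
random fixation targets and constant-velocity saccades.  There is no rate
noise, no main-sequence saccade kinematics, no head or hand signals, no
multiple-object scenes, and no recurrence among output neurons.  Passing
tests therefore demonstrate properties of the model under its own idealized
conditions — the emergence and width-dependence of gain-field shapes — not
quantitative agreement with recorded cortical variability.

## Known limitations

- The multiplicativity statistic is strict at its 5 % default: even the
  hardwired edge-neuron examples reach residuals ≈ 0.12 at their
  strongest-gain fixation, so "approximately multiplicative" families can
  fail the default threshold.
- The profile classifier is a plumbing heuristic; its thresholds are
  conventions, not fitted quantities.
- Self-organized neuron identities are stochastic; analyses therefore
  always quantify over the population, never over individual output
  indices.
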