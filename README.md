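# gainfield

Simulations of **eye-position gain fields**: how the position of the eyes
multiplicatively modulates the responses of retinotopic visual neurons, as
observed throughout the primate dorsal visual pathway (parietal areas 7a,
LIP, V6A, PO).  The package is aimed at computational neuroscientists who
want a small, fully reproducible rate-model testbed for gain modulation —
both a closed-form "hardwired" population and a learning model that
self-organizes the same response repertoire.

## The models

**Hardwired population.**  A single layer of visual neurons tiles the joint
space of preferred retinal location α ∈ [−10°, 10°] and preferred eye
position β ∈ [−35°, 35°] in 1° steps (21 × 71 = 1491 neurons).  Each
neuron's internal activation sums two Gaussian components,

    h(x, y) = h_max,r · exp(−(x − α)² / 2σ²) + h_max,e · exp(−(y − β)² / 2ρ²),

and its firing rate is the sigmoid `v = 1 / (1 + exp(−2φ(h − θ)))` with
slope φ = 1.9, threshold θ = 0.99, h_max = 0.485 for both components,
σ = 6° and ρ = 20° by default.  Gaussian eye-position tuning (rather than
the linear gain functions of earlier basis-function models) is the point:
it yields a *variety* of gain-field shapes — peaked, sigmoidal, nearly
linear — without violating Dale's law, while leaving each neuron's
retinotopic preference untouched.

**Self-organizing network.**  92 Gaussian-tuned input units (71 eye-position
units, 21 retinal units; φ = 4.5, θ = 0, h_max = 2, ρ = 15° default) feed
100 leaky-integrator output neurons (τ = 100 ms, Forward–Euler step τ/10)
through a sparse non-negative weight matrix (each output samples 10 % of the
inputs).  Output competition subtracts the population's 90th-percentile
activation p_π inside the sigmoid, so about 10 % of outputs are active at a
time.  Weights grow Hebbianly (`dw_ij/dt = ϱ v_i v_j`, ϱ = 0.05) and each
output's weight vector is renormalized to unit length after every update.
Training presents randomized fixation/saccade sequences (15 fixations of
300 ms at random integer eye positions, joined by 14 saccades at 400°/s,
for each of the 21 retinal stimulus locations, over 10 epochs).

**Analyses.**  Tuning-curve linearity is the coefficient of determination
R² of an ordinary least-squares line fit of rate against eye position;
multiplicativity is tested by finding, per fixation, the scale constant
that best maps the straight-ahead retinal-sweep curve onto that fixation's
curve and measuring the worst relative L2 residual; profiles are classified
monotonic / peaked / unresponsive.

## Worked example

```python
import gainfield as gf

grid = gf.build_population()            # 1491 neurons, default parameters
for alpha, beta in [(-10, -34), (-5, -18), (0, 0), (5, 18), (10, 34)]:
    curve = gf.eye_sweep(gf.HardwiredNeuron(alpha, beta), grid)
    r2 = gf.linearity_r2(curve).r_squared
    print(alpha, beta, round(r2, 3))
```

prints

```
-10 -34 0.877
-5 -18 0.818
0 0 0.0
5 18 0.818
10 34 0.877
```

Edge-of-range neurons (β = ±34°) see only the rising flank of their
eye-position Gaussian across the tested range, so their gain fields are
nearly linear (R² ≈ 0.88); the central neuron's symmetric, peaked gain
field has R² = 0 exactly.  The same sweep from the shell:

```sh
$ gainfield hardwired sweep --alpha -10 --beta -34 --out sweep.csv
# alpha=-10.0 beta=-34.0 R^2=0.8767
```

Other entry points: `gainfield hardwired linearity` (population R² table),
`gainfield selforg train --seed 1 --rho 15 --out results/run1` (training,
checkpoint + log + per-output summary), `gainfield analyze curves.csv`
(user-supplied tuning-curve tables), and `gainfield reproduce <experiment>`
for the canned bundles `fig2_curves`, `fig3_rho_sweep`,
`fig4_multiplicativity`, `selforg_train`, `fig7_rho_sweep`,
`fig9_multiplicativity`.

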