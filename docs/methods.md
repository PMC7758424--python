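# Methods

## Model overview

`memdec` simulates a system-level architecture for memory-based decision
making with five interacting components:

1. **Perceptual scanning.** A scene contains objects `O_i` at spatial
   locations, each a set of attributes `a_ij`; an attended attribute emits a
   fixed binary feature vector of length `F`. While attention dwells on an
   object, one of its attributes is chosen uniformly at random and re-drawn
   every `dwell_attr` steps (default 20).
2. **Memory.** A recurrent network over the feature space with per-connection
   delays. The state `x` follows the Euler-integrated dynamics

       dx_i/dt = −leak·x_i + I_i + Σ_j (1 − d_ji) w_ji f(x_j(t − τ_ji))

   with a saturating piecewise-linear activation `f(x) = clip(x, 0, 1)`.
   Semantic (auto- and hetero-associative) weights act at latency
   `tau_fast` (default 1 step) and produce attractor settling; episodic
   hetero-associative weights act at latency `tau_slow` and replay stored
   sequences, moving the state into predicted future states. Per-connection
   synaptic depression

       d_ji ← clip(d_ji + dt·(g_d · w_ji · f(x_j) · (1 − d_ji) − g_r · d_ji), 0, 1)

   is a Tsodyks-style resource depletion: it grows with the signal flowing
   through the connection, collapses the current attractor after a dwell,
   and so drives latching transitions between semantically associated
   states. Depression survives memory resets and recovers at rate `g_r`.
3. **Valuation.** A linear map `V = v · m` over the memory readout
   `m = f(x)`. Value mass sits on the feature elements of valued patterns so
   that the readout of a settled attractor returns exactly the scenario's
   stated value.
4. **Accumulation and decision.** One leaky competing accumulator per
   location:

       dx_i/dt = −λ·x_i + α·I_i − β·Σ_{j≠i} I_j + γ·f(x_i) − δ·Σ_{j≠i} f(x_j) + N(σ)

   where `I_i = V` for the attended location and 0 otherwise, `f` is ReLU,
   and noise is i.i.d. Gaussian per accumulator per step scaled by `√dt`.
   The four gains are forward excitation (α), forward inhibition (β),
   feedback excitation (γ) and feedback inhibition (δ); β and δ route
   through an inhibitory inter-node and therefore enter with a minus sign
   even though all gains are stored non-negative. A winner-takes-all
   decision layer fires when an accumulator reaches threshold (1 throughout),
   breaking exact ties uniformly at random; it then resets the accumulators
   and locks attention on the winner. Reaction time is the step count from
   trial onset to the crossing; no non-decision time is added.
5. **Spatial attention.** At every step attention may shift to location `i`
   with probability

       p_i = ε (s_i + φ g_i^n) / Σ_j (s_j + φ g_j^n)

   where `s` is binary object salience, `g` the ReLU accumulator output,
   φ the top-down gain and `n = 2` the contrast exponent. The `p_i` sum to
   ε, the base shift rate; a draw landing on the current location counts as
   a dwell continuation (no reset). A shift to a different object resets the
   memory state (depression excepted) and samples a fresh attribute, as does
   a within-dwell re-draw that lands on a different attribute.

A trial loops attention → memory → valuation → accumulation → decision until
threshold or `max_steps` (timeout, reported separately from decided trials).
Batches seed trial `i` with `base_seed + i` so any single trial is
independently reproducible.

## Design choices in open territory

- **Feature geometry.** Patterns are orthogonal one-hot blocks (block size 1
  by default). Orthogonality makes attractor encoding exact and lets the
  value map hit stated values exactly at settled readouts; a block `overlap`
  parameter exists for semantic-similarity experiments.
- **Memory leak.** The raw memory dynamics carry no decay term, and the
  module default is `leak = 0` (a constant input then integrates as a pure
  ramp). All bundled scenarios set `leak = 0.2`: without decay an attractor's
  activation grows without bound and a collapsed attractor never releases its
  nodes, so latching and per-attribute value alternation require a relaxation
  path. The saturating `f` keeps readouts bounded either way.
- **Discrete time.** `dt = 1` defines the simulation cycle; delays are ring
  buffers in whole steps. The accumulator's continuous leak λ maps to the
  discrete-time shrinkage factor `λ_discrete = 1 − λ·dt`.
- **Depression and delays.** Depression states are kept per weight matrix
  (semantic and episodic separately); with depression disabled, a weight
  matrix behaves identically whether routed through the fast or the slow
  pathway when `tau_slow = tau_fast`, which the tests exploit as an exact
  equivalence oracle.
- **Attention cadence.** The shift rule is evaluated once per step. Attention
  only targets occupied locations.

## Calibration of the bundled presets

Scenario-defining numbers — the option values (0.4/0.6, 0.2/0.8, mirrored
0.2/0.3, 0.9 vs 1.0), threshold 1, contrast exponent 2, binary salience —
are fixed by the experimental designs. Every dynamical gain is a repository
calibration chosen once to put the architecture in the regime the
experiments describe, then frozen:

- **Direct-value family (fig5a, fig5b, fig7, fig10).** ε = 0.5, α = 0.015
  (0.03 for the two-attribute scenario, whose mean per-dwell value is half),
  λ = 0.004, σ = 0.02, γ = δ = β = 0. Fast attention alternation makes the
  per-location value inputs average out quickly, and the leak places the
  accumulator equilibria `α·V/(2λ)` just below threshold, so crossings are
  noise-driven. This is the regime in which the canonical accumulator
  phenomenology appears: near-certain choice of the higher value at low
  noise, probabilities sliding toward 0.5 and reaction times shrinking as σ
  grows, a speed–accuracy trade-off under forward inhibition, right-skewed
  reaction-time distributions with the less-preferred option slower and more
  dispersed.
- **Episodic family (fig9a, fig9b).** ε = 0.08, τ_slow = 2, α = 0.004,
  λ = 0.002, σ = 0.005, unit input gain and episodic strength. Each episodic
  transition costs ≈ τ_slow + settling ≈ 3 steps of a dwell whose length is
  geometric with continuation rate 1 − ε/2, so the expected valued time per
  dwell scales as exp(−μ·k·T) with μ = ε/2: an effective exponential
  discount with no discount parameter anywhere in the configuration (the
  scenario schema is asserted to contain no such key). With these constants
  a delayed reward of 1.0 loses to an immediate 0.9 from k = 2 transitions
  on, the calibrated break-off point.

## What the scenario generator emulates — and what it does not

`make_scenario` builds the study conditions as declarative worlds:
orthogonal attribute patterns, pre-set semantic/episodic/value associations,
binary salience. It emulates the *structure* of the experiments, not real
perception: there are no images, no graded or correlated features, no
learning of the associations (they are pre-set by construction), no arousal
modulation of memory randomness. Passing tests therefore show that the
architecture produces the claimed system-level phenomena under idealized
encodings; they say nothing about performance on real stimuli or about how
such associations would be acquired.

## Numerical choices

- Explicit Euler throughout; all times in simulation steps.
- Depression clipped to [0, 1] after every update.
- Non-finite states raise immediately with the offending step and nodes
  (checked via one NaN/inf-propagating reduction per step).
- Exact accumulator ties at threshold are broken uniformly with the trial's
  seeded generator.
- Degenerate scenes (no salience and no feedback anywhere) are an error, not
  a silent uniform fallback.
- Accumulator states may go negative (ReLU applies to outputs only) unless
  `clamp_state` is enabled.
- Timeouts default to `max_steps = 10,000` (20,000 for the slower episodic
  family); timed-out trials are excluded from reaction-time summaries and
  counted separately.

## Problem sizes

Validation experiments use two-object scenes with feature dimensionalities
of 2–12 (one element per pattern), 500–2,000 trials per condition, and
3-point parameter grids for the noise, inhibition and feedback sweeps; the
discounting experiment runs 1,000 trials at each chain length 0–9. These
sizes put every batch in the seconds-to-minutes range on one core while
keeping binomial standard errors below ~1.6 percentage points.

## Known limitations

- No learning anywhere: associations and values are pre-set; conditioning
  and reinforcement-learning interfaces are out of scope.
- Salience is binary object presence; no image-based saliency.
- Arousal/neuromodulatory control of memory randomness is not modeled (an
  additive memory-noise hook exists but defaults to 0).
- Memory→perception priming, value→memory and value→spatial-attention
  interactions are not modeled.
- Figure-level quantitative shapes depend on the preset calibrations; only
  the qualitative trends are parameter-robust, and the discounting
  break-off point in particular is a calibration target.
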