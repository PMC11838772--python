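# Methods

This note documents the models, conventions and synthetic benchmarks in
`trajedit`: what is computed, under which assumptions, and why each design
choice that was genuinely open was made the way it was. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## 1. The editing model

### Problem

An entity (cell, patient) is observed as a `V × T` matrix of continuous
variables at strictly increasing times, with an observation mask. An *edit
request* supplies a history window ending at `t_i`, an optional condition
token `s`, and a target time `t_j > t_i`. *Immediate* editing is
`t_j = t_i+1`; *delayed* editing is any larger gap, answered in a single
generation step.

### Architecture

`x̂[:, t_j] = c ⊙ x[:, t_i]` with
`c = GELU(FFN(h_x ⊙ (Δ(t_i, t_j) + h_s)))`.

- **Sequence encoder** (`h_x`, dimension `d_h`): default is a single-layer
  gated recurrent unit over per-step inputs `(values, mask, time
  embedding)` with final-state readout; a single-head self-attention
  encoder with mean-pooled readout is the drop-in alternative. These are
  the smallest members of the two encoder families the contract allows;
  any encoder emitting a `d_h` summary can be plugged in.
- **Time encoder**: `h_t` is the element-wise sum of a fixed sinusoidal
  embedding of the year (standard alternating sin/cos, base wavelength
  10 000) and learned lookup tables for month (12), day-of-month (31) and
  hour (24). Sub-hour structure is not encoded. The month/date/hour
  components are learned tables rather than sinusoids because their
  domains are finite, which avoids aliasing. Integer step indices are
  interpreted as hours from a fixed epoch (2000-01-01), giving simulated
  step data full calendar semantics; this also means step indices never
  alias (24 steps roll into the next day rather than wrapping).
- **Condition adapter**: conditions are frozen vectors `z_s` from a token
  table (standing in for any pretrained embedding model); the adapter is
  one affine layer plus GELU, `d_z → d_h`, with the bias initialized at 1.
  The adapted condition gates the history representation multiplicatively
  in the concept encoder, so a near-zero initial `h_s` would throttle the
  encoder's gradient and the encoder then collapses to a constant
  representation (observed reproducibly on worlds whose concepts depend on
  history); starting with the gate open — the same reasoning as
  initializing LSTM forget-gate biases high — removes the failure. A
  reserved null token carries a *learned* embedding so "no condition" is
  distinguishable from an all-zero pretrained vector. The frozen vectors
  are never updated — tested bit-exactly.
- **Concept encoder**: the FFN is one affine layer `d_h → V`; a
  configuration flag removes it, in which case `d_h` must equal `V`
  (enforced at build time). GELU is the exact erf form; every concept
  entry is therefore bounded below by the GELU infimum ≈ −0.16997.
- **Concept decoder**: exact element-wise product, applied once per
  forecast regardless of the gap (instrumented by a decode counter).

### Working range and scaling

The decoder is multiplicative and the GELU bounds concepts below ≈ −0.17,
so sign changes and zero crossings are not representable in raw space. All
modeling therefore happens after a per-variable min-max affine map onto
`[ε_pos, 1]` (`ε_pos = 0.01` by default); constant variables map to the
midpoint 0.5 with unit scale so the map stays invertible. The map
round-trips to ≤ 1e−9 relative error and all reported metrics are computed
after inverting it. The concept's exact ratio interpretation
(`c = x[:, t_j] ⊘ x[:, t_i]`) holds in the scaled range; to compare learned
concepts with generative ground truth we report *implied raw-space rates*:
invert the scaling on the prediction and divide by the raw value at `t_i`.

### Loss, training, missing data

Training minimizes the mean Huber loss (`δ = 1`, averaged — not summed —
over mask-true coordinates so `δ` has a consistent meaning across `V`).
The optimizer is Adam with default moments; learning rate, batch size,
epochs and patience live in `TrainConfig`. Train/validation splits are by
entity (never by window), early stopping watches validation loss, and the
best-validation checkpoint is returned. Delayed-editing training shares
the immediate-editing forward path exactly; when the horizon set has
several gaps, one gap is drawn uniformly per example per epoch. Missing
cells contribute nothing to the loss and enter the encoder only through
the mask channel. Every random draw descends from the config seed; two
runs with the same seed produce bit-identical loss curves and parameters.

### Bit-exact time-delta algebra

`Δ(t_i, t_j) = h_{t_j} − h_{t_i}` must satisfy `Δ(t,t) = 0`, antisymmetry
and additivity. Antisymmetry is exact in IEEE arithmetic, but additivity
`Δ(a,b) + Δ(b,c) = Δ(a,c)` is not, in general, bit-exact for arbitrary
float64 embeddings. All time-embedding components are therefore snapped to
multiples of 2⁻²⁶ (straight-through gradient): sums and differences of a
handful of such values up to magnitude ~2⁶ incur no rounding, so the whole
delta algebra holds bit-exactly. The snap perturbs values by < 1.5e−8 and
is irrelevant to learning.

### Autodiff engine

No trainable-network library is part of the package's dependency
footprint; the models are small, so `trajedit.autodiff` implements a
compact tape-based reverse-mode engine over float64 numpy arrays (matmul,
broadcasting arithmetic, GELU/sigmoid/tanh, embedding lookup, softmax
cross-entropy, Huber, gradient reversal). Every operator's gradient is
finite-difference tested, including through the recurrent and attention
encoders end to end.

## 2. Baselines and ablations

- **SimpleLinear / LOCF**: the all-ones-concept ablation — the prediction
  is the last observation, for any target time and condition. Exactly
  equivalent to `decode_concept(ones, x_last)`.
- **VAR(p)**: pooled ordinary least squares across entities (default
  `p = 1`), solved by `lstsq` (pseudo-inverse under rank deficiency, with a
  warning); conditions are ignored. Rollout feeds predictions back and
  reports divergence as infinities rather than failing — an unstable VAR
  blowing up at long horizons is a documented behavior, not an error.
- **Autoregressive comparator**: the same sequence encoder, time encoder
  and condition adapter as the editor, but a plain regression head
  (`h → V`) instead of the concept bottleneck and multiplicative decoder.
  It must be applied `g` times to reach gap `g`, so the contrast with the
  editor isolates exactly the concept mechanism plus one-step generation.

## 3. Counterfactual prediction and balancing

`tau_step_predict` estimates τ-step-ahead outcomes under a planned
treatment sequence by iterating the one-step conditional forecast,
conditioning each step on the next planned token and appending the
prediction to the rolling history. The assumptions are the standard ones
for counterfactual prediction from observational sequences (consistency,
positivity, sequential ignorability), plus the modeling assumption that
the concept decoder approximates the conditional mean of the next outcome
given history and the next treatment; none of these are testable from data
and they are documented rather than enforced.

`balanced_train` adds an adversarial treatment classifier (one affine
layer + softmax over the treatment vocabulary) on the history
representation `h_x`, connected through a gradient-reversal unit (forward
identity, backward negate-and-scale). Design choices that stabilize the
min-max game, each adopted after observing its failure mode in piloting:

- **Warm-up ramp**: the reversal strength follows
  `λ_t = λ · W · (2/(1+e^{−10p}) − 1)` with `p` the training progress;
  switching the adversary on abruptly drives representations into a
  confidently-wrong (anti-predictive) regime that still leaks treatment
  information.
- **Relative weight** `W = 0.1`: the cross-entropy term is O(1) while the
  Huber term in the scaled range is O(10⁻³); without a fixed relative
  weight, `λ = 1` would let the adversary dominate the encoder entirely.
  `λ` thus expresses pressure relative to a moderate default.
- **Separate, faster head optimizer** so the classifier tracks the moving
  representations.
- **Checkpoint selection inside the fully-ramped final third**: selecting
  by forecast loss over all epochs systematically prefers the
  least-balanced early epochs. An optional `checkpoint_metric` hook lets
  callers select by a task metric instead; the balancing benchmark selects
  by τ-rollout MAE on training entities, because the epoch with the best
  one-step loss is demonstrably not always the best roll-forward model.

**How balance is scored.** We report the held-out accuracy of the model's
own treatment-classifier head: for `λ = 0` (plain training) a converged
affine-softmax readout of the frozen representations, for `λ > 0` the
jointly trained adversary — the quantity the balancing literature reports.
A caveat stated plainly: a probe *retrained to convergence* on the balanced
representations can still recover residual treatment information; plain
gradient reversal suppresses its own adversary, not every decoder. Users
who need certified removal of information need stronger tools than
reversal.

`λ = 0` disables balancing and is bit-identical to plain training under
the same seed (tested).

**Concept intervention**: `intervene_concept` multiplies targeted concept
entries by positive factors, leaving the rest bit-unchanged; because the
decoder is multiplicative, a factor `f` on variable `k` scales exactly
that variable's one-step prediction by `f`. `intervened_rollout`
recomputes the concept from the rolling history at every step and
re-applies the factors — a *persistent* intervention, chosen because a
sustained counterfactual regime is the natural reading of simulating a
modified patient forward; a one-shot intervention is recovered by rolling
out manually. Cohort similarity between a generated and a reference
trajectory is a pooled R², with each shared variable scaled by the
reference's standard deviation before pooling so variables with different
units contribute comparably.

## 4. Synthetic worlds

### Multiplicative world

`x_{t+1} = r_s ⊙ x_t ⊙ exp(σ η_t)` with standard normal `η`. Per-condition
rate vectors are drawn once per world from U(0.9, 1.1) per variable — large
enough that last-observation carry-forward is clearly beatable, small
enough that 30-step trajectories stay within a few orders of magnitude;
the null condition drifts mildly (U(0.98, 1.02)). Initial values are
U(1, 10); condition embeddings are fixed random Gaussian vectors per world
seed. The true concept between any two steps is the product of per-step
rates, so parameter recovery is exactly measurable. Factual/counterfactual
pairs share one noise stream: both arms evolve under condition *a* before
the divergence step, arm *b* switches to `r_b` after it, so the arms are
bit-identical before divergence and the contrast is exact.

What it emulates: condition-dependent multiplicative dynamics with known
ground truth. What it does not: regime switches within an entity,
missingness, irregular sampling, heavy-tailed noise. Passing tests here
shows the mechanism works when its assumptions hold; it does not certify
performance on real EHR data.

### Tumor-growth world

Daily volume update
`V(t+1) = V(t)·(1 + ρ log(K/V(t)) − β_c C(t) − (α_r d(t) + β_r d(t)²) + ε_t)`,
the standard logistic-growth pharmacokinetic-pharmacodynamic form: chemo
concentration `C` decays exponentially (half-life 1 day) and jumps by a
fixed dose on administration; radiotherapy delivers `d = 2` Gy at
treatment days. Patient parameters are drawn from uniform priors
(`ρ` ∈ [0.05, 0.15]/day, `β_c` ∈ [0.02, 0.04], `α_r` ∈ [0.03, 0.05]/Gy,
`β_r = α_r/10`); the carrying capacity corresponds to a 13 cm diameter;
initial diameters are U(6, 12) cm; noise is additive Gaussian
(σ = 0.02) on the growth increment. Every constant lives in
`DEFAULT_TUMOR_CONFIG` and is recorded in each dataset's metadata.

Treatment assignment each day is Bernoulli with probability
`sigmoid(γ · (d̄ − 9 cm)/3 cm)`, where `d̄` is the mean diameter over the
last 3 days: `γ = 0` is a fair coin (unconfounded), larger `γ` ties
treatment to tumor burden. Centering at the typical diameter with a 3 cm
scale gives `γ` a full dynamic range over the simulated population.
Treated days are split evenly between chemo and radio. The observed
concentration covariate is the *pre-dose* (morning) level so a day's own
treatment is never encoded in that day's covariates.

Counterfactual ground truth re-runs the same patient (same parameters,
same noise stream) under an alternative planned sequence; benchmark
splits provide single-sliding plans (one treatment at each offset) and
uniformly random plans. Under a plan the concentration channel is a
deterministic function of the doses, so counterfactual evaluation feeds
the known planned concentration into the rolling history rather than the
model's guess — it is part of the treatment input, not an outcome.

## 5. Benchmark problem sizes

The reproduction experiments (`trajedit.experiments`, also driven by
`scripts/acceptance.py`) use desk-scale worlds chosen so each study runs
in minutes on one CPU while leaving clear margins on its effects:

- concept recovery: V = 5, 200 entities, T = 30, 3 conditions, σ = 0,
  `d_h = 64` recurrent encoder, 25 epochs;
- delayed editing and counterfactual divergence: the same world at
  σ = 0.1, editor trained on horizons 1–14, comparator on gap 1, 15
  epochs; evaluation at gaps 5 and 10 from three history cutoffs, and on
  40 factual/counterfactual pairs diverging at step 10;
- confounding and balancing: 100 patients for the γ-grid diagnostics, 500
  patients at γ = 4 for the balancing comparison (`d_h = 16`, 25 epochs) —
  adversarial games at a few thousand windows are visibly noisier.

## 6. Known limitations

- Concepts cannot express rates below the GELU infimum (≈ −0.17); the
  positive working range makes this moot for the shipped scalers, but a
  custom scaler mapping data near zero re-exposes it.
- The multiplicative decoder cannot move a variable whose value at `t_i`
  is exactly the working-range floor by more than the floor times the
  concept ceiling; min-max scaling keeps observed data away from zero.
- `evaluate` reports R² as NaN when the truth has no variance, and cohort
  similarity does the same for flat references — markers, not errors.
- The comparator approximates, but does not replicate, published
  conditional-generation baselines; conclusions about "rollout versus
  one-step" are architecture-internal contrasts.
- Gradient-reversal balancing defeats its own classifier; it does not
  certify that no decoder can recover treatment information (see §3).
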