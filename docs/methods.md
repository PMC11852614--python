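# Methods

## Model

`choicesim` simulates a sequential decision-maker that balances reward
against *choice consistency* — the tendency to repeat the choices it has
made before for similar stimuli.

At each discrete step *k* the agent:

1. samples a stimulus *s* ~ Normal(0, σ_s²);
2. samples an action *a* ∈ {1, …, N_a} from its policy
   P(a | s, w) ∝ Σ_{i=1}^{N_w} exp(−(a − (w_i⁰ + w_i¹ s))² / 2σ_a²),
   a mixture of N_w Gaussians whose means depend linearly on the stimulus,
   evaluated at the integer action locations and renormalized over them;
3. samples a reward *r* ~ Normal(μ(a, s), σ_r²) with
   μ(a, s) = α (a − β) s by default (with α = 2, β = 3/2 this rewards
   action 1 on negative stimuli and action 2 on positive ones; a plain
   additive form αa + βs is available via `EnvParams(reward_form="additive")`);
4. appends (s, a, r) to a FIFO memory of the last Δ triples;
5. once the memory is full, re-estimates the weight vector w by minimizing
   the compromise loss
   l_λ(w) = λ l_r(w) + (1 − λ) l_a(w),
   where l_a(w) = −Σ_j ln P(a_j | s_j, w) is the summed surprisal of the
   remembered actions under the candidate policy and
   l_r(w) = −E_s[Σ_a P(a | s, w) μ(a, s)] is the negative Bayes expected
   reward of the policy under the stimulus prior s ~ N(0, σ_s²).

At λ = 0 the agent cares only about being consistent with its own past; at
λ = 1 only about rewards.

## Emergent phenomena

With the standard parameters (w⁰ = (1.5, 0), N_w = 1, N_a = 2, Δ = 20,
λ = 0, σ_s = σ_a = σ_r = 1) the starting policy is exactly symmetric: every
choice is a coin flip. Surprisal minimization amplifies whatever imbalance
the first random choices produce — a spontaneous symmetry breaking. The
typical run develops *full discrimination* (each action elicited by its own
half of the stimulus axis), visible as a collapse of the consistency-loss
trace from its warmup maximum (Δ·ln 2 ≈ 13.9) to a low plateau. The broken
state is itself unstable: the boundary between the actions drifts until one
action is never sampled again. The last step at which a losing action is
sampled is its *stoppage time*.

## Loss and objective choices

- **Sum, not mean, for l_a.** The consistency loss grows as the memory
  window fills, matching the observed climb-then-collapse loss trace; the
  minimizer is unaffected by the constant factor at λ = 0.
- **Prior expectation for l_r** (`reward_loss_form="prior"`, the default):
  the reward term integrates over the stimulus prior N(0, σ_s²) by 41-node
  Gauss–Hermite quadrature rather than averaging over the remembered
  stimuli. This choice is load-bearing for the reward-dominated regime.
  Under a window average, the window-mean stimulus is nonzero
  (±σ_s/√Δ), so a stimulus-*blind* constant-action policy earns reward
  from it; the simplex search — whose default initial simplex perturbs a
  zero slope entry by only 0.00025 against 5% for the intercept — then
  always runs away along the intercept and terminates on that saturated
  plateau, and a λ = 1 agent never discriminates. Under the prior, the
  reward mean is odd in s, so every stimulus-blind policy scores exactly
  zero and the slope is the only descent direction; a λ = 1 agent then
  behaves as the reward design dictates (action 2 for positive stimuli,
  both actions sampled forever). Window-empirical forms remain available
  (`"mean"`, `"sum"`), as does a sampled-history variant
  (`sampled_reward_loss`). All forms use the analytic reward mean — the
  reward model is Normal, so its Bayes expectation is its mean.
- Probabilities are floored at 1e−300 before logs so that a candidate
  policy that excludes a remembered action costs a huge but finite value
  the optimizer can retreat from.

## Optimizer

Weights are re-fit each step with Nelder–Mead (the Lagarias et al.
simplex), tolerances 1e−6 (x and f), at most 200·dim iterations. Because
the search runs at every simulated step, the inner loop uses a compiled
port of scipy's Nelder–Mead (same initial-simplex construction, update
coefficients 1, 2, ½, ½, and termination rule); the test suite asserts it
reaches the same minima as `scipy.optimize.minimize(method="Nelder-Mead")`
on random problem instances. The simplex is re-initialized each step
**at the initial weight vector w⁰** (`simplex_start="initial"`).

This start-point choice was the one genuinely open design decision, and it
is load-bearing. Warm-starting at the previous step's weights
(`simplex_start="previous"`, also available) freezes the dynamics: once the
memory window is separable the summed surprisal at the incumbent is already
~0, the simplex converges immediately, the decision boundary never drifts,
and no action is ever eliminated — contradicting the defining behavior of
the model (a winner always emerges, and weights plateau at moderate values
rather than running away). Re-initializing at w⁰ restores the expected
phenomenology and is the default.

Even so, the per-step fit reaches an essentially deterministic (near-step)
policy, which makes the boundary drift a slow random walk. The simulated
stoppage-time distribution is therefore shifted to later times and is wider
than the scale this class of model can also produce under shallower
per-step fits; the stoppage-time *ordering* across conditions (longer
memory ⇒ later stoppage; more actions ⇒ later stoppage; larger λ ⇒ later
stoppage) is robust, the absolute scale is sensitive to optimizer depth,
which nothing in the model pins down. We deliberately did not tune
optimizer depth to produce any particular stoppage scale.

## Behavior classifier

The taxonomy (full_discrimination, intermingled, sandwich, switching,
non_discriminating) is defined only by description in the literature; the
operational rules here are:

- **Rolling blocks.** The post-warmup record is scanned in windows of 100
  steps (stride 50). A window counts as *organized* in either of two ways:
  - *clean separation*: every action present and < 15% of any action's
    stimuli inside another action's band span (5th–95th percentile);
  - *ordered medians*: every action present and the per-action median
    stimuli monotone in the action index with each adjacent gap beyond ~2
    SE of a median difference. This second route is essential for three or
    more actions: with σ_a equal to the unit action spacing even the
    optimal segmenting policy is probabilistically soft, so adjacent
    actions always share stimulus mass and pointwise sets never separate —
    yet the running-average choice map is clearly banded. The analogous
    ordering on |s| (one action nested between the flanks of another)
    counts as a sandwich. A lone ordered-median window can be sampling
    noise, so soft hits must recur in ≥ 2 windows (a clean window is
    sufficient alone).
- **Bands.** An action's stimuli are split into bands only at gaps that are
  both wide (> 4× the median spacing) and actually occupied by another
  action's stimuli — empty Gaussian-tail gaps are not band boundaries.
  Bands need ≥ 10% of the action's samples; smaller clusters count as
  strays.
- **non_discriminating:** one action's sampling frequency exceeds 0.95 in
  *every* block — there was never a discrimination phase.
- **switching:** organized blocks exist whose dominance direction (sign of
  median(s|a=2) − median(s|a=1), with a ~2-SE noise guard) differs over
  time.
- **intermingled:** no block is ever organized before the takeover.
- **full_discrimination vs sandwich:** judged from the last organized
  block (the settled arrangement closest to the takeover).

All thresholds are fields of `ClassifierOptions`. The classifier is
validated against a 500-trajectory synthetic bank built from known
generating rules (≥ 95% required agreement).

Stoppage times use the raw action records only: an action sampled within
the final Δ steps is censored (a winner); any other action's stoppage is
its last-occurrence index. Censored runs are excluded from stoppage means
and reported separately.

## Problem sizes

Batch statistics use 40 independent runs per condition (seeds
seed_base + i). Run lengths: T = 600 for Δ = 20 two-action conditions,
T = 1500 for Δ = 40 and N_a = 3 (three standard deviations of headroom
beyond the expected stoppage scale), and T = 800 for N_a ∈ {4, 5}, where
only the discrimination rate — assessed before or at the first stoppage —
is measured. The λ sweep uses the two-action standard configuration per
grid point.

## What the synthetic-data generator does and does not emulate

All inputs are generated internally by the model itself (stimuli, actions,
rewards); there is no external data. The generator realizes exactly the
stationary, one-dimensional, Gaussian world of the model: no
stimulus-distribution drift, no bounded or discrete stimulus sets (as a
laboratory experiment would have), no interoceptive channel, and no
between-agent coupling. Passing tests therefore demonstrate the internal
consistency and emergent statistics of the model — not that human choice
data behave this way.

## Known limitations

- The absolute stoppage-time scale depends on the per-step optimization
  depth (see above); comparisons across conditions are the reliable output.
- The classifier's block length (100 steps) limits sensitivity to
  switching episodes shorter than ~50 steps.
- For N_a > 6 and the standard σ_a, full discrimination is essentially
  never achieved; the classifier then reports intermingled/partial labels
  driven by whichever actions survive.
- `PolicyCollapseError` can only arise from numerically overflowing
  weights (|w| ≳ 1e154); the optimizer's warning at |w| > 1e3 fires long
  before that regime.
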