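# Methods

## The model

`crmn` simulates a modular, hierarchical architecture in which perception,
action, learning, and an operational consciousness readout are all organised
by a single quantity: the per-module **responsibility signal**.

The cortex-like substrate is a grid of modules addressed by (modality *i*,
level *k*).  Each module owns a **conjugate model pair**: a
forward/generative model *g* and an inverse/inference model *f* of the same
object.  In the sensory stream, *f* maps a raw representation one level up
(analytic, one-shot inference) and *g* maps an abstract representation one
level down (generation of the rawer representation); in the motor stream the
directions are reversed — *f* is the controller taking a desired state to a
command (the command issued at level *k* **is** the desired state of level
*k−1*), and *g* predicts the achieved state from the lower-level state and
the command.  When a pair matches the world, the cascade of the generative
model and its inverse is the identity, so the Euclidean **mismatch** between
the pair's two estimates is zero.

A prefrontal gating network (the cognitive reality monitoring network)
combines each module's mismatch `m_ik` with its reward prediction error
`delta_ik` into a cognitive prediction error

    e_ik^2 = m_ik^2 + w * delta_ik^2,

turns the errors into softmax likelihoods

    L_ik = exp(-e_ik^2 / sigma^2) / sum_lm exp(-e_lm^2 / sigma^2),

multiplies high-level likelihoods by a learned prior, renormalizes to obtain
the responsibility simplex `lambda`, and reads out the entropy

    S = -sum lambda ln lambda   (nats).

`lambda` gates everything: action blending, conjugate-pair learning rates,
reinforcement-learning updates, and the teaching signal of its own prior.
Low entropy (one dominant module) is the operational criterion for conscious
involvement; the argmax module is the object of metacognition.

## Design choices where the formulation is open

* **Model classes.** Affine maps (default) and one-hidden-layer tanh maps.
  The functional form of *f* and *g* is unspecified in the model; affine is
  the smallest class in which modules can specialize per linear context and
  in which every convergence claim can be checked against closed forms.
* **Concatenated recurrent inputs.** The inference and generative maps each
  receive both the bottom-up and the top-down estimate of their input level
  (`f(x, x̂)`, `g(x, x̂)`), as concatenated vectors.  Top-down estimates are
  initialized to zero before the first pass.  Recurrence lives *within* one
  settle cycle (`recurrent_settle`, default 2 iterations); carrying top-down
  state across environment steps proved numerically unstable (the learned
  recurrent loop has no stationary input distribution) and is not done in
  the shipped experiments.
* **Train/measure consistency.** Gated pair learning takes one gradient step
  on the squared mismatch of the *exact* composition that produced the
  measured mismatch: the inference pass caches the precise input each
  inverse model consumed (`SignalBoard.f_in_cache`), and the gradient flows
  through both *g* and *f*.  Without this, SGD optimizes a slightly
  different composition than the one measured and the mismatch plateaus at
  ~2e-2 instead of reaching numerical zero on noiseless data.
* **Prior placement and scaling.** "High levels" is operationalized as level
  ordinal ≥ `level_prior_min` (default: top level only).  Because the
  prior-times-likelihood product is renormalized over the *whole* module
  set, the prior is first scaled to mean one over the modules it applies to;
  a uniform (uninformative) prior is then exactly neutral.  The prior
  estimator *h* is an affine-plus-softmax map over concatenated high-level
  representations, zero-initialized (uniform output), trained by
  cross-entropy with the responsibility vector as the teaching signal; it
  never sees error signals.
* **Norms and logs.** All mismatch norms are Euclidean; entropy is in nats.
* **Readout.** `conscious = S <= theta_S` with default
  `theta_S = 0.5 ln(N_modules)`; ties in the argmax break to the lowest
  module index.

## The synthetic worlds

The generator realizes the smallest worlds in which responsibility gating is
identifiable; per-context parameters are validated at construction by a
closed-form separation criterion (white-input regression error for plants,
cross-subspace projection residual for sensory maps).

* **Switching plant (motor stream).**  `s' = A_c s + B_c u + eta`,
  `eta ~ N(0, 0.02^2 I)`, 2-D state and command.  Two contexts differing in
  damping, rotation, and input gain (`A_0 = 0.85 R(0.45), B_0 = I`;
  `A_1 = 0.40 R(-0.55), B_1 = 0.55 R(0.9)`), context switching every 125
  steps, hidden from the agent.  Reward is the negative squared distance of
  the new state to a context-dependent goal on the unit circle.  2500 steps
  per run, 10 seeds.
* **Switching sensory stream.**  `o = W_c z + eta`, `z ~ N(0, I_2)`,
  `o` 4-D, `eta ~ N(0, 0.05^2 I)`.  Three contexts rendering through
  near-equidistant 2-D subspaces (span(e0,e1), span(e2,e3), and the diagonal
  span; pairwise cross-subspace residuals sqrt(2), 1, 1), switching every
  100 steps; 2500 training steps.  Three contexts rather than two because
  the isolated-activation probe's entropy prediction needs at least two
  remaining candidate modules once the probed module is ruled out.

What these worlds do **not** emulate: non-linear or non-Gaussian dynamics,
observation aliasing, slow context drift, reward sparsity, or any biological
noise structure.  Passing tests therefore demonstrate the gating and readout
*mechanisms*, not performance on realistic sensorimotor data.

## The experiment loop (motor)

Per step: the policy mixture (responsibility-weighted over per-modality
actors) picks a goal prototype; a norm-capped reference governor turns it
into this step's desired state; each modality's controllers produce a
candidate command; the responsibility-blended command plus exploration
dither (sigma 0.3) is executed; every module then predicts the outcome from
the *executed* command, and the gate scores:

* level 0: `m = ||s_observed' − g(s, u)||` — desired-vs-achieved read at the
  module's proprioceptive (sensory) interface.  The pure motor form
  `||x_d − x̂||` with each module's own internal command is *anti*-
  discriminative: a mismatched module's forward model confirms its own
  controller.  Grounding the comparison in the sensed outcome is the
  sensory-stream mismatch of the same module and is what makes context
  identification possible.
* level 1: `m = ||x_d − x̂_1||` with the achieved-state estimate re-grounded
  in the sensed state, so the common tracking error cancels across modules
  in the softmax.

Reward prediction errors use the TD machinery in its myopic afterstate form
(`gamma = 0`, critic over quadratic features `[s, ||s||^2, 1]` evaluated at
the state just reached): `delta = r − V(s')`, literally predicted-minus-
actual reward.  With bootstrapped full-gamma TD and a stochastic prototype
policy, `delta^2` is dominated by action-selection noise, which drowned the
small mismatch differences that drive early specialization; the myopic form
is lag-free, exactly representable by the quadratic critic, and strongly
context-discriminative (the default `w = 0.1` then measurably improves both
identification and reward over mismatch-only gating).

Learning is responsibility-gated supervised regression (normalized LMS:
step size `lr/(1+||z||^2)`, which keeps closed-loop online learning stable
at any signal magnitude): forward models on observed transitions, level-0
controllers by direct inverse modelling (observed `(s, s', u) -> u`), plus
gated TD/actor updates and the prior's cross-entropy step.

**Persistence.** Learning and action selection use an exponentially smoothed
responsibility (EMA weight 0.3).  The instantaneous responsibility — the
defining formula, and what the logs and metrics report — flips on per-step
sensor noise while modules are still similar; without the low-pass filter no
module accumulates the persistent advantage that competitive specialization
needs, and the grid converges to identical "average" experts.  The smoothing
delays adaptation after a context switch by ~1/0.3 ≈ 3 steps against a
125-step dwell time.

## Gate hyperparameters (shipped defaults)

| parameter | motor | sensory | meaning |
|---|---|---|---|
| sigma | 0.1 | 0.35 | softmax temperature, units of cognitive error; a few times the sensor-noise floor so noise-level differences do not saturate the gate |
| w | 0.1 | 0 | reward-error weight (reward units → representation units); 0 in the passive sensory stream (no reward) |
| level_prior_min | 1 | 1 | prior applies at the top level |
| theta_S | 0.5 ln N | 0.5 ln N | consciousness threshold |
| gate smoothing | 0.3 | 0.3 | EMA weight of the operative responsibility |

`GateConfig` itself defaults to the neutral `sigma = 1, w = 1`; the
experiment specs carry their own values, and the `sweep` CLI verb explores
the (sigma, w) grid.

## Metrics

Context identification is the post-burn-in (first 20% of steps discarded)
agreement between the argmax-responsibility module's modality and the hidden
context, scored under the optimal one-to-one modality↔context assignment:
emergent specialization fixes no labelling (either permutation is an equally
valid solution), so raw argmax agreement would score a perfect permuted
solution at 0.  The uniform-gate ablation still scores only the majority
context share under this metric.  Prior recovery is prequential: at each
step the prior's argmax (trained only on earlier steps) is compared with the
current dominant module.  The confidence/reward-error coupling is the
Spearman rank correlation between the maximum responsibility and the
dominant module's squared reward prediction error; in this synthetic design
it sits near zero, because the gate and the reward error react within the
same time step — the lagged, decoded-signal character that produces the
negative empirical relation has no analogue here, and no result depends
on it.

## Probes

* **Isolated activation.**  After sensory training, a strong pattern (norm
  3) is injected at the responsible module's top level with the clamp on (no
  coherent input); the comparison cycle presents a 5-frame stimulus from the
  active context (single frames can be genuinely ambiguous when they fall
  near the shared direction of two context subspaces).  Prediction: the
  targeted module's mismatch rises, its responsibility collapses, and the
  responsibility entropy rises relative to the coherent cycle — induced
  information strong enough to matter behaviourally, yet non-conscious by
  the entropy criterion.
* **Sense of agency.**  A self-generated movement (own command, own forward
  prediction) is compared with an externally imposed movement of matched
  magnitude during which no command was issued: predicting from a null
  command cannot account for the observed motion, the mismatch is large, and
  the agency attribution is withheld.

## Numerical notes

* Likelihoods are computed with max-subtraction and explicitly renormalized
  (raw log-sum-exp arithmetic leaves ~1e-12 residue at extreme logits; the
  explicit division holds the simplex to ~1e-16).
* Degenerate gates (all prior-times-likelihood products zero) raise an
  error rather than silently uniformizing.
* Commands are norm-clipped at 4 (actuator bound); the reference governor
  caps the per-step goal offset at 0.8, keeping one-step inverse control in
  the well-modelled regime (without it, model error occasionally destabilizes
  the loop and the run never recovers).
* All randomness descends from one integer seed through
  `numpy.random.SeedSequence` fan-out; a run is a pure function of
  (spec, seed) and re-runs are byte-identical.

## Problem sizes

The shipped studies use 2-D plants / 4-D observations, 2–3 contexts,
2500-step runs, and 10 seeds per condition; these are the smallest
configurations in which every mechanism (specialization, ablation ordering,
prior recovery, both probes) is identifiable and stable across seeds.

## Known limitations

* Affine experts cannot represent strongly non-linear contexts; the MLP
  class is provided but the shipped studies are linear.
* The responsibility prior reads state-dependent features, so it identifies
  contexts through where they drive the state, not through dynamics per se;
  in worlds where contexts share their state distribution it would stay
  uninformative.
* The depth-summed cognitive-error variant (aggregating a column's
  mismatches across levels) is available in spirit via `include_levels`
  but a per-column aggregation operator is not implemented.
* No stochastic/Bayesian formulation: all passes are deterministic maps, as
  in the deterministic formulation the architecture is stated in.
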