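# crmn

A runnable simulator of a **cognitive reality monitoring network**: a
modular hierarchy of paired generative/inverse models whose selection,
learning, and an entropy-based metacognition/consciousness readout are all
driven by per-module **responsibility signals**.

## Who this is for

Computational neuroscientists and researchers in modular/hierarchical
reinforcement learning who want a small, fully seeded, testable
implementation of mixture-of-experts-style responsibility gating extended
with (a) conjugate forward/inverse model pairs whose *internal consistency*
(rather than an external teaching signal) drives gating, (b) per-module
reward prediction errors entering the gate, and (c) an entropy readout over
the responsibility simplex as an operational criterion for conscious
involvement.

## The model in brief

Each module (modality *i*, level *k*) holds a forward/generative model *g*
and an inverse/inference model *f* of the same object; a matched pair
composes to the identity, so the mismatch `m_ik` between its two estimates
vanishes exactly when the module fits the current world.  The gate combines
mismatches with reward prediction errors `δ_ik` into cognitive errors and
responsibilities:

```
e_ik² = m_ik² + w·δ_ik²
L_ik  = exp(−e_ik²/σ²) / Σ_lm exp(−e_lm²/σ²)
λ_ik  ∝ λ̂_ik·L_ik   (high levels; λ_ik ∝ L_ik below)
S     = −Σ λ_ik ln λ_ik
```

The responsibility simplex `λ` gates action blending, model learning, and
reinforcement learning, and teaches its own prior `λ̂ = h(high-level
representations)`.  Low entropy `S` means one module dominates — the
operational consciousness criterion; the argmax module is the object of
metacognition.

Two synthetic worlds exercise the architecture: a hidden-context switching
linear plant (motor stream: which internal model should control right now?)
and a switching linear-Gaussian observation stream (sensory stream: which
generative model explains the input?).  Isolated-activation and
sense-of-agency probes test the readout's signature predictions.
See `docs/methods.md` for the full account.

## Worked example

```python
from crmn import default_motor_spec, run_experiment

spec = default_motor_spec(seeds=[0])     # two-context switching plant
result = run_experiment(spec)
print(result.metrics[0].to_dict())
```

prints (abridged):

```
context_accuracy : 0.9975     # argmax-λ identifies the hidden context
prior_accuracy   : 0.8335     # h predicts the dominant module (chance 0.25)
mean_mismatch    : 0.0688     # λ-weighted pair mismatch, post burn-in
entropy_final    : 0.0424     # S ≈ 0: one module dominates → "conscious"
mean_reward      : -1.51
```

After gated training, each candidate module has specialized to one hidden
context: the responsibility signal names the active context on 99.75% of
post-burn-in steps, the prior predicts the responsible module from abstract
representations alone, and the responsibility entropy is near zero.

The decoded-neurofeedback-style probe injects a strong but isolated pattern
into the currently responsible sensory module (no coherent stimulus):

```python
from crmn import default_sensory_spec, probe_comparison
print(probe_comparison(default_sensory_spec(), seed=0))
```

```
target m2k1   coherent: mismatch 0.64  λ 1.000  S 0.0000
              probe:    mismatch 4.78  λ 0.000  S 0.6931
```

The induced representation is strong, yet its conjugate pair receives no
related input from above or below: the mismatch explodes, responsibility
collapses, entropy rises — the pattern stays below the consciousness
criterion, reproducing the signature prediction for isolated activations.

## Command line

```bash
crmn build-config --kind motor -o spec.yaml   # emit a default experiment
crmn run -c spec.yaml -o runs/                # execute; logs + metrics
crmn report runs/motor-context-seed0.csv      # recompute metrics from a log
crmn probe -c sensory.yaml --kind decnef      # isolated-activation probe
crmn probe -c spec.yaml    --kind agency      # sense-of-agency probe
crmn sweep -c spec.yaml --sigma 0.1 --w 0.0 --w 0.1   # gate-parameter grid
```

Run logs are columnar CSV (one row per step, every gate signal per module)
plus line-delimited JSON; a run is a pure function of (spec, seed).

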