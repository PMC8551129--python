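"""Experiment runners: the closed perceive -> gate -> act -> learn loop,
ablations, and summary metrics.

Two shipped experiment kinds:

* ``motor_context`` — the default two-context switching plant.  One motor
  modality per candidate context competes to control the plant; the gate
  routes learning and action by responsibility.  Reinforcement learning
  selects among goal prototypes; the inverse models turn the chosen goal
  into commands.
* ``sensory_context`` — a switching linear-Gaussian observation stream; one
  sensory modality per candidate context learns a generative/inference pair
  of its context's rendering map.  This is the substrate for the
  isolated-activation probes.

A run is a pure function of (spec, seed): identical inputs give
byte-identical run logs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Any

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .conjugate import compute_mismatches, gated_pair_update, motor_bottomup_pass, motor_topdown_pass, recurrent_settle
from .core import (
    ConfigurationError,
    GridConfig,
    ModuleGrid,
    RunLog,
    StepSnapshot,
    build_grid,
)
from .environments import (
    PlantConfig,
    SensoryConfig,
    SwitchingPlant,
    SwitchingSensoryWorld,
)
from .gate import GateConfig, PriorEstimator, gate_step
from .rl import gated_rl_update, select_action, td_error


class AblationFlags(BaseModel):
    uniform_gate: bool = False  # responsibility forced uniform everywhere
    w_zero: bool = False  # mismatch-only gating (reward errors ignored)
    prior_off: bool = False  # responsibility prior held uniform
    hard_selection: bool = False  # argmax module instead of blended mixture


class ExperimentSpec(BaseModel):
    """Fully serializable description of one experiment."""

    name: str = "motor-context"
    kind: str = "motor_context"  # "motor_context" | "sensory_context"
    env: dict[str, Any] = Field(default_factory=dict)
    gate: GateConfig = Field(default_factory=GateConfig)
    n_steps: int = 2000
    seeds: list[int] = Field(default_factory=lambda: list(range(10)))
    burn_in: float = 0.2
    n_iters: int = 1  # recurrent settling depth per step (sensory kind)
    lr_pair: float = 0.08
    lr_value: float = 0.05
    lr_policy: float = 0.2
    lr_prior: float = 0.05
    command_bound: float = 4.0  # actuator limit: commands are norm-clipped
    gate_smoothing: float = 0.2  # EMA weight on the instantaneous responsibility
    explore_noise: float = 0.3  # command dither; keeps the plant persistently excited
    goal_step: float = 0.8  # reference governor: per-step norm cap on the pursued goal offset
    selection: str = "blend"
    ablations: AblationFlags = Field(default_factory=AblationFlags)

    def env_config(self):
        if self.kind == "motor_context":
            return PlantConfig(**self.env)
        if self.kind == "sensory_context":
            return SensoryConfig(**self.env)
        raise ConfigurationError(f"unknown experiment kind {self.kind!r}")


def default_motor_spec(**overrides: Any) -> ExperimentSpec:
    """The default two-context switching-plant experiment."""
    base: dict[str, Any] = dict(
        name="motor-context",
        kind="motor_context",
        env={"n_contexts": 2, "switch_period": 125, "noise": 0.02},
        gate=GateConfig(sigma=0.1, w=0.1, level_prior_min=1),
        n_steps=2500,
        lr_pair=0.08,
        lr_value=0.2,
        gate_smoothing=0.3,
    )
    base.update(overrides)
    return ExperimentSpec(**base)


def default_sensory_spec(**overrides: Any) -> ExperimentSpec:
    """The default three-context switching sensory stream (probe substrate)."""
    base: dict[str, Any] = dict(
        name="sensory-context",
        kind="sensory_context",
        env={"n_contexts": 3, "switch_period": 100, "noise": 0.05},
        gate=GateConfig(sigma=0.35, w=0.0, level_prior_min=1, include_levels=[1]),
        n_steps=2500,
        n_iters=2,
        lr_pair=0.1,
        gate_smoothing=0.3,
    )
    base.update(overrides)
    return ExperimentSpec(**base)


# --------------------------------------------------------------------------- #
# Metrics
# --------------------------------------------------------------------------- #


@dataclass
class MetricsReport:
    n_steps: int
    context_accuracy: float
    prior_accuracy: float
    mean_mismatch: float
    mean_mismatch_per_module: dict[str, float]
    mean_abs_delta: float
    entropy_mean: float
    entropy_final: float
    mean_reward: float
    coupling: float | None
    coupling_note: str

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _empty_report(note: str = "empty log") -> MetricsReport:
    return MetricsReport(
        n_steps=0,
        context_accuracy=0.0,
        prior_accuracy=0.0,
        mean_mismatch=0.0,
        mean_mismatch_per_module={},
        mean_abs_delta=0.0,
        entropy_mean=0.0,
        entropy_final=0.0,
        mean_reward=0.0,
        coupling=None,
        coupling_note=note,
    )


def _modality_of(key: str) -> int:
    return int(key[1 : key.index("k")])


def summarize(log: RunLog, burn_in: float = 0.2) -> MetricsReport:
    """Metrics computed from the run log alone.

    Context identification compares the modality of the argmax-responsibility
    module with the true hidden context, after a burn-in fraction (learning
    transients are not gating failures).  Confidence/reward-error coupling is
    the rank correlation between max responsibility and the squared reward
    prediction error of the dominant module.
    """
    if len(log) == 0:
        return _empty_report()
    df = log.to_dataframe()
    n = len(df)
    start = int(np.floor(burn_in * n))
    post = df.iloc[start:]
    resp_cols = sorted(c for c in df.columns if c.startswith("responsibility_"))
    keys = [c[len("responsibility_"):] for c in resp_cols]
    resp = post[resp_cols].to_numpy()
    argmax_idx = resp.argmax(axis=1)
    argmax_modality = np.array([_modality_of(keys[j]) for j in argmax_idx])
    truth = post["true_context"].to_numpy()
    # emergent specialization fixes no module <-> context labelling, so
    # identification accuracy is scored under the best one-to-one assignment
    # (standard for unsupervised switching-system segmentation)
    modalities = sorted(set(_modality_of(k) for k in keys))
    contexts = sorted(set(int(c) for c in truth))
    conf = np.zeros((len(modalities), len(contexts)))
    for a, b in zip(argmax_modality, truth):
        conf[modalities.index(int(a)), contexts.index(int(b))] += 1
    rows, cols = linear_sum_assignment(-conf)
    accuracy = float(conf[rows, cols].sum() / len(truth))

    prior_cols = [f"prior_{k}" for k in keys]
    prior = post[prior_cols].to_numpy()
    prior_accuracy = float(np.mean(prior.argmax(axis=1) == argmax_idx))

    mism_cols = [f"mismatch_{k}" for k in keys]
    mism = post[mism_cols].to_numpy()
    weighted_mismatch = float(np.mean(np.sum(resp * mism, axis=1)))
    per_module = {k: float(post[c].mean()) for k, c in zip(keys, mism_cols)}

    delta_cols = [f"delta_{k}" for k in keys]
    deltas = post[delta_cols].to_numpy()
    mean_abs_delta = float(np.mean(np.sum(resp * np.abs(deltas), axis=1)))

    tail = df.iloc[int(np.floor(0.8 * n)):]
    max_resp = resp.max(axis=1)
    sel_delta_sq = deltas[np.arange(len(post)), argmax_idx] ** 2
    if np.ptp(max_resp) == 0.0 or np.ptp(sel_delta_sq) == 0.0:
        coupling, note = None, "degenerate variance: constant confidence or delta"
    else:
        rho = stats.spearmanr(max_resp, sel_delta_sq).statistic
        coupling, note = (None, "undefined") if np.isnan(rho) else (float(rho), "ok")
    return MetricsReport(
        n_steps=n,
        context_accuracy=accuracy,
        prior_accuracy=prior_accuracy,
        mean_mismatch=weighted_mismatch,
        mean_mismatch_per_module=per_module,
        mean_abs_delta=mean_abs_delta,
        entropy_mean=float(post["entropy"].mean()),
        entropy_final=float(tail["entropy"].mean()),
        mean_reward=float(post["reward"].mean()),
        coupling=coupling,
        coupling_note=note,
    )


# --------------------------------------------------------------------------- #
# Motor-context runner
# --------------------------------------------------------------------------- #


def _motor_grid_config(env_cfg: PlantConfig, seed: int) -> GridConfig:
    return GridConfig(
        n_modalities=env_cfg.n_contexts,
        level_dims=[env_cfg.dim, env_cfg.dim],
        streams="motor",
        input_dim=env_cfg.dim,
        command_dim=env_cfg.dim,
        n_actions=env_cfg.n_contexts + 1,
        value_features="quadratic",
        gamma=0.0,
        seed=seed,
    )


def _run_motor(spec: ExperimentSpec, seed: int, return_state: bool = False):
    env_seed, grid_seed, act_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(3)
    )
    env_cfg = spec.env_config().model_copy(update={"seed": env_seed})
    env = SwitchingPlant(env_cfg)
    grid = build_grid(_motor_grid_config(env_cfg, grid_seed))
    rng = np.random.default_rng(act_seed)

    gate_cfg = spec.gate
    if spec.ablations.w_zero:
        gate_cfg = gate_cfg.model_copy(update={"w": 0.0})
    n_levels = grid.n_levels
    top = n_levels - 1
    mids = grid.module_ids()
    keys = [str(m) for m in mids]
    ordinals = np.array([m.level.ordinal for m in mids])
    n_modules = len(mids)
    n_mod = grid.n_modalities

    prototypes = env.goals + [np.zeros(env_cfg.dim)]
    d = env_cfg.dim
    h = PriorEstimator(in_dim=d + n_mod * d + 1, n_modules=n_modules)

    lam = np.full(n_modules, 1.0 / n_modules)
    s = env.reset(env_seed)
    for i in range(n_mod):
        grid.prime_motor(i, s)

    log = RunLog(seed)
    selection = "argmax" if spec.ablations.hard_selection else spec.selection
    for t in range(spec.n_steps):
        mod_lam = np.array([sum(lam[j] for j in range(n_modules) if mids[j].modality == i)
                            for i in range(n_mod)])
        mod_lam = mod_lam / mod_lam.sum()
        policies = [grid.slot(i, top).rl.prefs for i in range(n_mod)]
        action, _ = select_action(policies, mod_lam, rng, mode=selection)
        x_d_top = prototypes[action]
        # reference governor: walk toward the chosen goal in bounded steps so
        # one-step inverse control stays in the well-modeled regime
        offset = x_d_top - s
        dist = float(np.linalg.norm(offset))
        if dist > spec.goal_step:
            x_d_top = s + offset * (spec.goal_step / dist)

        commands = []
        for i in range(n_mod):
            motor_topdown_pass(grid, x_d_top, modality=i)
            commands.append(grid.slot(i, 0).board.command)
        if selection == "argmax":
            u = commands[int(np.argmax(mod_lam))]
        else:
            u = sum(w * c for w, c in zip(mod_lam, commands))
        if spec.explore_noise > 0.0:
            u = u + spec.explore_noise * rng.standard_normal(u.shape)
        u_norm = float(np.linalg.norm(u))
        if u_norm > spec.command_bound:
            u = u * (spec.command_bound / u_norm)

        s_next, reward, info = env.step(u)

        mism: dict[str, float] = {}
        for i in range(n_mod):
            grid.slot(i, 0).board.command = u  # ground predictions in the executed command
            motor_bottomup_pass(grid, s, modality=i)
            for k in range(n_levels):
                slot = grid.slot(i, k)
                if k == 0:
                    # proprioceptive consistency: sensed outcome vs predicted state
                    m = float(np.linalg.norm(s_next - slot.board.top_down))
                else:
                    # desired vs achieved abstract state; the upward estimate is
                    # re-grounded in the sensed outcome once it is available, so
                    # a module cannot flatter its own controller with its own
                    # forward model
                    slot.board.top_down = slot.pair.forward(
                        np.concatenate([s_next, slot.board.command])
                    )
                    m = float(np.linalg.norm(slot.board.desired - slot.board.top_down))
                mism[str(slot.module_id)] = m

        deltas: dict[str, float] = {}
        for mid in mids:
            slot = grid.slots[mid]
            # myopic afterstate form: the critic predicts the reward of the
            # state just reached, so delta is the literal predicted-minus-actual
            # reward mismatch, free of action-selection noise
            deltas[str(mid)] = td_error(slot.rl, s_next, reward, s_next, terminal=True)

        z = np.concatenate(
            [x_d_top] + [grid.slot(i, top).board.top_down for i in range(n_mod)] + [[1.0]]
        )
        prior = None
        if not (spec.ablations.prior_off or spec.ablations.uniform_gate):
            prior = h.predict(z)

        m_vec = np.array([mism[k] for k in keys])
        d_vec = np.array([deltas[k] for k in keys])
        state = gate_step(keys, m_vec, d_vec, ordinals, gate_cfg, n_levels, prior=prior)
        if spec.ablations.uniform_gate:
            lam_inst = np.full(n_modules, 1.0 / n_modules)
            entropy_val = float(np.log(n_modules))
        else:
            lam_inst = state.responsibility
            entropy_val = state.entropy
        # persistence: learning and selection run on a low-passed responsibility,
        # so momentary sensor noise cannot flip the winner within a context block
        beta = spec.gate_smoothing
        lam = (1.0 - beta) * lam + beta * lam_inst
        lam = lam / lam.sum()

        mod_lam_new = np.array([sum(lam[j] for j in range(n_modules) if mids[j].modality == i)
                                for i in range(n_mod)])
        for i in range(n_mod):
            lam_i = float(mod_lam_new[i])
            s0 = grid.slot(i, 0)
            s1 = grid.slot(i, top)
            if lam_i > 0.0:
                eff = spec.lr_pair * lam_i
                s0.pair.forward.sgd_step(np.concatenate([s, u]), s_next, eff, normalized=True)
                s0.pair.inverse.sgd_step(
                    np.concatenate([s_next, s0.board.top_down, s]), u, eff, normalized=True
                )
                s1.pair.forward.sgd_step(
                    np.concatenate([s_next, s1.board.command]), s_next, eff,
                    normalized=True,
                )
                s1.pair.inverse.sgd_step(
                    np.concatenate([x_d_top, s1.board.top_down, s0.board.top_down]),
                    x_d_top,
                    eff,
                    normalized=True,
                )
        for j, mid in enumerate(mids):
            slot = grid.slots[mid]
            act = action if mid.level.ordinal == top else None
            gated_rl_update(
                slot.rl, deltas[keys[j]], float(lam[j]), spec.lr_value, s_next,
                action=act, lr_policy=spec.lr_policy, normalized=True,
            )
        if not spec.ablations.prior_off:
            h.update(z, lam, spec.lr_prior)

        log.append(
            StepSnapshot(
                step=t,
                seed=seed,
                true_context=int(info["context"]),
                selected_module=keys[int(np.argmax(lam_inst))],
                action=int(action),
                reward=float(reward),
                entropy=entropy_val,
                mismatch=mism,
                delta=deltas,
                cog_error=dict(zip(keys, state.e)),
                likelihood=dict(zip(keys, state.likelihood)),
                prior=dict(zip(keys, state.prior)),
                responsibility=dict(zip(keys, lam_inst)),
            )
        )
        s = s_next
    if return_state:
        return log, grid, env, lam
    return log


# --------------------------------------------------------------------------- #
# Sensory-context runner
# --------------------------------------------------------------------------- #


def _sensory_grid_config(env_cfg: SensoryConfig, seed: int) -> GridConfig:
    return GridConfig(
        n_modalities=env_cfg.n_contexts,
        level_dims=[env_cfg.obs_dim, env_cfg.latent_dim],
        streams="sensory",
        input_dim=env_cfg.obs_dim,
        n_actions=2,
        seed=seed,
    )


def train_sensory_grid(
    spec: ExperimentSpec, seed: int
) -> tuple[ModuleGrid, SwitchingSensoryWorld, RunLog]:
    """Run the sensory-context experiment; returns the trained grid too, so
    probes can be run against it."""
    env_seed, grid_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)
    )
    env_cfg = spec.env_config().model_copy(update={"seed": env_seed})
    env = SwitchingSensoryWorld(env_cfg)
    grid = build_grid(_sensory_grid_config(env_cfg, grid_seed))
    gate_cfg = spec.gate
    n_levels = grid.n_levels
    mids = grid.module_ids()
    ordinals_all = np.array([m.level.ordinal for m in mids])
    if gate_cfg.include_levels is not None:
        sel = np.isin(ordinals_all, gate_cfg.include_levels)
    else:
        sel = np.ones(len(mids), dtype=bool)
    gate_mids = [m for m, s_ in zip(mids, sel) if s_]
    keys = [str(m) for m in gate_mids]
    ordinals = ordinals_all[sel]
    n_mod = grid.n_modalities

    log = RunLog(seed)
    lam_s = np.full(len(keys), 1.0 / len(keys))
    for t in range(spec.n_steps):
        obs, _, info = env.step()
        for i in range(n_mod):
            # recurrence lives within the settle cycle; no cross-step carryover
            for slot in grid.modality_slots(i):
                slot.board.clear()
            recurrent_settle(grid, obs, n_iters=spec.n_iters, modality=i)
        mism_all = compute_mismatches(grid)
        m_vec = np.array([mism_all[k] for k in keys])
        state = gate_step(
            keys, m_vec, np.zeros_like(m_vec), ordinals, gate_cfg, n_levels, prior=None
        )
        if spec.ablations.uniform_gate:
            lam = np.full(len(keys), 1.0 / len(keys))
            entropy_val = float(np.log(len(keys)))
        else:
            lam = state.responsibility
            entropy_val = state.entropy
        beta = spec.gate_smoothing
        lam_s = (1.0 - beta) * lam_s + beta * lam
        lam_s = lam_s / lam_s.sum()
        lam_by_mod = {m.modality: float(v) for m, v in zip(gate_mids, lam_s)}

        for i in range(n_mod):
            lam_i = lam_by_mod.get(i, 1.0 / n_mod)
            if lam_i == 0.0:
                continue
            slots = grid.modality_slots(i)
            for k in range(n_levels):
                slot = slots[k]
                lower_bu = obs if k == 0 else slots[k - 1].board.bottom_up
                own_td = slot.board.top_down
                own_td = own_td if own_td is not None else np.zeros(slot.board.dim)
                gated_pair_update(
                    slot.pair,
                    f_in=slot.board.f_in_cache,
                    target=lower_bu,
                    responsibility=lam_i,
                    lr=spec.lr_pair,
                    g_post=own_td,
                )

        zeros = {k: 0.0 for k in keys}
        log.append(
            StepSnapshot(
                step=t,
                seed=seed,
                true_context=int(info["context"]),
                selected_module=keys[int(np.argmax(lam))],
                action=0,
                reward=0.0,
                entropy=entropy_val,
                mismatch={k: float(v) for k, v in zip(keys, m_vec)},
                delta=dict(zeros),
                cog_error=dict(zip(keys, state.e)),
                likelihood=dict(zip(keys, state.likelihood)),
                prior=dict(zip(keys, state.prior)),
                responsibility=dict(zip(keys, lam)),
            )
        )
    return grid, env, log


def probe_comparison(
    spec: ExperimentSpec, seed: int, strength: float = 3.0, n_frames: int = 5
) -> dict[str, Any]:
    """Train the sensory grid, then contrast a coherent stimulus with an
    isolated-activation probe of the currently responsible module.

    The coherent cycle presents a short stimulus sequence from the active
    context's rendering map; the probe injects a pattern of norm ``strength``
    at that module's top level with no coherent input.  Returns the
    per-condition target mismatch, target responsibility and entropy.
    """
    from .core import ModuleId
    from .environments import DecNefProbe, gate_cycle, run_decnef_probe

    grid, env, _ = train_sensory_grid(spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]).generate_state(1)[0])
    ctx = env.context
    latents = rng.standard_normal((n_frames, env.config.latent_dim))
    obs = latents @ env.maps[ctx].T
    coherent = gate_cycle(grid, spec.gate, obs, n_iters=spec.n_iters)
    top = grid.n_levels - 1
    target_key = coherent.module_keys[int(np.argmax(coherent.responsibility))]
    idx = coherent.module_keys.index(target_key)
    target_modality = _modality_of(target_key)
    pattern = rng.standard_normal(grid.config.level_dims[top])
    pattern = strength * pattern / np.linalg.norm(pattern)
    probe = run_decnef_probe(
        grid,
        spec.gate,
        DecNefProbe(target=ModuleId(target_modality, grid.levels[top]), pattern=pattern),
        n_iters=spec.n_iters,
        n_frames=n_frames,
    )
    return {
        "target_module": target_key,
        "coherent": {
            "mismatch": float(coherent.e[idx]),
            "responsibility": float(coherent.responsibility[idx]),
            "entropy": float(coherent.entropy),
        },
        "probe": {
            "mismatch": float(probe.e[idx]),
            "responsibility": float(probe.responsibility[idx]),
            "entropy": float(probe.entropy),
        },
    }


def agency_comparison(spec: ExperimentSpec, seed: int) -> dict[str, Any]:
    """Contrast self-generated movement with externally imposed motion.

    Sense of agency is modelled as low motor-stream mismatch that requires
    both a top-down intention and the matching bottom-up motion.  After
    training on the switching plant, a self-generated step (the agent's own
    command moved the plant) is compared with an imposed step of matched
    magnitude during which the agent issued no command: the forward models,
    predicting from a null command, cannot account for the observed motion,
    so the mismatch is large and no module claims responsibility.
    """
    log, grid, env, lam = _run_motor(spec, seed, return_state=True)
    n_mod = grid.n_modalities
    # re-identify the responsible module from a fresh dithered transition (the
    # training run may have ended on a context switch)
    rng0 = np.random.default_rng(np.random.SeedSequence([seed, 12]).generate_state(1)[0])
    s_pre = env.state.copy()
    u_dither = spec.explore_noise * rng0.standard_normal(env.config.dim)
    s_post, _, _ = env.step(u_dither)
    errs = [
        float(
            np.linalg.norm(
                s_post
                - grid.slot(i, 0).pair.forward(np.concatenate([s_pre, u_dither]))
            )
        )
        for i in range(n_mod)
    ]
    responsible = int(np.argmin(errs))
    s = env.state.copy()
    goal = env.contexts[env.context].goal
    offset = goal - s
    dist = float(np.linalg.norm(offset))
    x_d = s + offset * (min(dist, spec.goal_step) / dist) if dist > 0 else s

    # self-generated: the responsible module's own command moves the plant
    grid.prime_motor(responsible, s)  # refresh the raw state estimate
    motor_topdown_pass(grid, x_d, modality=responsible)
    u_self = grid.slot(responsible, 0).board.command.copy()
    u_norm = float(np.linalg.norm(u_self))
    if u_norm > spec.command_bound:
        u_self *= spec.command_bound / u_norm
    s_next, _, _ = env.step(u_self)
    pred_self = grid.slot(responsible, 0).pair.forward(np.concatenate([s, u_self]))
    m_self = float(np.linalg.norm(s_next - pred_self))

    # imposed: matched-magnitude external push, the agent issues no command
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]).generate_state(1)[0])
    u_ext = rng.standard_normal(len(u_self))
    u_ext *= np.linalg.norm(u_self) / np.linalg.norm(u_ext)
    s2 = env.state.copy()
    s2_next, _, _ = env.step(u_ext)
    pred_null = grid.slot(responsible, 0).pair.forward(
        np.concatenate([s2, np.zeros_like(u_self)])
    )
    m_imposed = float(np.linalg.norm(s2_next - pred_null))
    return {
        "responsible_module": f"m{responsible}k0",
        "self_mismatch": m_self,
        "imposed_mismatch": m_imposed,
        "agency_attributed": m_self < m_imposed,
    }


# --------------------------------------------------------------------------- #
# Entry points
# --------------------------------------------------------------------------- #


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    logs: dict[int, RunLog]
    metrics: dict[int, MetricsReport]

    @property
    def aggregate(self) -> dict[str, float]:
        if not self.metrics:
            return {}
        acc = [m.context_accuracy for m in self.metrics.values()]
        mm = [m.mean_mismatch for m in self.metrics.values()]
        ent = [m.entropy_final for m in self.metrics.values()]
        rew = [m.mean_reward for m in self.metrics.values()]
        return {
            "median_context_accuracy": float(np.median(acc)),
            "median_mean_mismatch": float(np.median(mm)),
            "median_entropy_final": float(np.median(ent)),
            "median_mean_reward": float(np.median(rew)),
        }


def run_experiment(spec: ExperimentSpec, out_dir: str | None = None) -> ExperimentResult:
    """Execute the full loop for every seed in the spec; optionally write the
    run logs (columnar table + line-delimited records) and a metrics summary."""
    spec.env_config()  # validate before any stepping
    if spec.kind not in ("motor_context", "sensory_context"):
        raise ConfigurationError(f"unknown experiment kind {spec.kind!r}")
    logs: dict[int, RunLog] = {}
    metrics: dict[int, MetricsReport] = {}
    for seed in spec.seeds:
        if spec.kind == "motor_context":
            log = _run_motor(spec, seed)
        else:
            _, _, log = train_sensory_grid(spec, seed)
        logs[seed] = log
        metrics[seed] = summarize(log, burn_in=spec.burn_in)
    result = ExperimentResult(spec, logs, metrics)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for seed, log in logs.items():
            log.to_csv(os.path.join(out_dir, f"{spec.name}-seed{seed}.csv"))
            log.to_jsonl(os.path.join(out_dir, f"{spec.name}-seed{seed}.jsonl"))
        with open(os.path.join(out_dir, f"{spec.name}-metrics.json"), "w") as fh:
            json.dump(
                {
                    "per_seed": {str(s): m.to_dict() for s, m in metrics.items()},
                    "aggregate": result.aggregate,
                },
                fh,
                indent=2,
            )
    return result
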