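"""Synthetic switching-context worlds and activation probes.

Two families of environments exercise the architecture:

* ``SwitchingPlant`` — a hidden context selects which 2-D linear dynamics
  (A_c, B_c) govern the plant and which goal earns reward (negative squared
  tracking error).  The classic multiple-internal-model setting: only the
  module whose models match the active dynamics can predict and control well.
* ``SwitchingSensoryWorld`` — a hidden context selects which linear map W_c
  renders a low-dimensional latent into observations (plus Gaussian noise).

The hidden context index is never exposed to the agent — only observations
and rewards; the true context is logged for evaluation.

``DecNefProbe`` models decoded-neurofeedback-style isolated activation: a
target module's representation is set externally while no coherent input is
presented.  The induced pattern is strong, but because neither the inverse
nor the generative model receives related input from below or above, the
pair mismatch is large, the module's responsibility collapses, and the
responsibility entropy rises — the representation stays nonconscious.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from pydantic import BaseModel, Field

from .core import ConfigurationError, ModuleGrid, ModuleId, ShapeError, as_representation
from .gate import GateConfig, GateState, gate_step
from .conjugate import compute_mismatches, recurrent_settle, sensory_generative_pass, sensory_inference_pass


def rotation2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


# --------------------------------------------------------------------------- #
# Switching linear plant (motor stream)
# --------------------------------------------------------------------------- #


class PlantConfig(BaseModel):
    """2-D switching linear plant.  Contexts differ in damping, rotation and
    input gain; separation between context dynamics is enforced at
    construction so that gating is identifiable."""

    n_contexts: int = 2
    dim: int = 2
    noise: float = 0.02
    switch_period: int = 125
    random_dwell: bool = False
    dwell_range: tuple[int, int] = (80, 170)
    min_separation: float = 0.3
    goal_radius: float = 1.0
    seed: int = 0


@dataclass
class PlantContext:
    A: np.ndarray
    B: np.ndarray
    goal: np.ndarray


def _default_plant_contexts(cfg: PlantConfig) -> list[PlantContext]:
    """Deterministic context battery: damping/rotation/gain spread evenly.

    Context c: A_c = rho_c R(theta_c), B_c = gain_c R(phi_c), goal on a
    circle of radius ``goal_radius``; values chosen so any two contexts are
    clearly distinguishable from one-step transitions.
    """
    n = cfg.n_contexts
    contexts = []
    for c in range(n):
        rho = 0.85 - 0.45 * c / max(n - 1, 1)
        theta = 0.45 - 1.0 * c / max(n - 1, 1)
        gain = 1.0 - 0.45 * c / max(n - 1, 1)
        phi = 0.9 * c / max(n - 1, 1)
        ang = 2.0 * np.pi * c / n + 0.4
        goal = cfg.goal_radius * np.array([np.cos(ang), np.sin(ang)])
        contexts.append(PlantContext(rho * rotation2(theta), gain * rotation2(phi), goal))
    return contexts


class SwitchingPlant:
    """Hidden-context 2-D linear plant:  s' = A_c s + B_c u + noise,
    reward = -|| s' - goal_c ||^2."""

    def __init__(self, config: PlantConfig, contexts: list[PlantContext] | None = None):
        if config.n_contexts < 2:
            raise ConfigurationError("a switching plant needs at least two contexts")
        self.config = config
        self.contexts = contexts if contexts is not None else _default_plant_contexts(config)
        if len(self.contexts) != config.n_contexts:
            raise ConfigurationError("context list length must equal n_contexts")
        self._validate_separation()
        self.reset(config.seed)

    def _validate_separation(self) -> None:
        # Closed-form one-step regression error of context d's exact model on
        # context c data with white (s, u): ||A_c - A_d||_F^2 + ||B_c - B_d||_F^2.
        for c in range(len(self.contexts)):
            for d in range(c + 1, len(self.contexts)):
                sep = np.linalg.norm(self.contexts[c].A - self.contexts[d].A) ** 2
                sep += np.linalg.norm(self.contexts[c].B - self.contexts[d].B) ** 2
                if np.sqrt(sep) < self.config.min_separation:
                    raise ConfigurationError(
                        f"contexts {c} and {d} are not distinguishable "
                        f"(separation {np.sqrt(sep):.3f} < {self.config.min_separation})"
                    )

    def reset(self, seed: int | None = None) -> np.ndarray:
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        self.state = np.zeros(self.config.dim)
        self.context = 0
        self.t = 0
        self._next_switch = self._draw_dwell()
        return self.state.copy()

    def _draw_dwell(self) -> int:
        if self.config.random_dwell:
            lo, hi = self.config.dwell_range
            return int(self.rng.integers(lo, hi + 1))
        return self.config.switch_period

    @property
    def n_contexts(self) -> int:
        return self.config.n_contexts

    @property
    def goals(self) -> list[np.ndarray]:
        return [ctx.goal.copy() for ctx in self.contexts]

    def step(self, command: np.ndarray) -> tuple[np.ndarray, float, dict[str, Any]]:
        u = as_representation(command, None, "command")
        if u.shape[0] != self.config.dim:
            raise ShapeError(
                f"command dimension {u.shape[0]} does not match plant input {self.config.dim}"
            )
        ctx = self.contexts[self.context]
        noise = self.config.noise * self.rng.standard_normal(self.config.dim)
        self.state = ctx.A @ self.state + ctx.B @ u + noise
        reward = -float(np.sum((self.state - ctx.goal) ** 2))
        self.t += 1
        info = {"context": self.context, "t": self.t, "switched": False}
        if self.t >= self._next_switch:
            self.context = (self.context + 1) % self.config.n_contexts
            self._next_switch = self.t + self._draw_dwell()
            info["switched"] = True
        return self.state.copy(), reward, info


# --------------------------------------------------------------------------- #
# Switching linear-Gaussian sensory world
# --------------------------------------------------------------------------- #


class SensoryConfig(BaseModel):
    """Observations are W_c z + noise with z ~ N(0, I); contexts differ in
    the rendering map W_c (subspaces rotated against each other)."""

    n_contexts: int = 3
    obs_dim: int = 4
    latent_dim: int = 2
    noise: float = 0.05
    switch_period: int = 100
    min_separation: float = 0.3
    seed: int = 0


def _default_sensory_maps(cfg: SensoryConfig) -> list[np.ndarray]:
    """Orthonormal rendering frames with large, near-symmetric pairwise
    subspace separation.

    For the default 3-context / 4-D case the subspaces are span(e0, e1),
    span(e2, e3) and the diagonal span((e0+e2), (e1+e3))/sqrt(2): pairwise
    cross-subspace reconstruction errors are sqrt(2), 1 and 1.  Other sizes
    fall back to evenly spread double-plane rotations of a base frame.
    """
    if cfg.n_contexts == 3 and cfg.obs_dim == 4 and cfg.latent_dim == 2:
        e = np.eye(4)
        w3 = np.stack([(e[0] + e[2]) / np.sqrt(2), (e[1] + e[3]) / np.sqrt(2)], axis=1)
        return [e[:, :2].copy(), e[:, 2:].copy(), w3]
    base = np.zeros((cfg.obs_dim, cfg.latent_dim))
    base[: cfg.latent_dim] = np.eye(cfg.latent_dim)
    maps = []
    for c in range(cfg.n_contexts):
        theta = np.pi / 2 * c / max(cfg.n_contexts, 1) + 0.45 * (c > 0)
        R = np.eye(cfg.obs_dim)
        R[np.ix_([0, 2], [0, 2])] = rotation2(theta)
        R2 = np.eye(cfg.obs_dim)
        R2[np.ix_([1, 3], [1, 3])] = rotation2(0.8 * theta)
        maps.append(R2 @ R @ base)
    return maps


class SwitchingSensoryWorld:
    """Hidden-context linear-Gaussian observation stream (no dynamics)."""

    def __init__(self, config: SensoryConfig, maps: list[np.ndarray] | None = None):
        if config.n_contexts < 2:
            raise ConfigurationError("a switching sensory world needs at least two contexts")
        self.config = config
        self.maps = maps if maps is not None else _default_sensory_maps(config)
        self._validate_separation()
        self.reset(config.seed)

    def _validate_separation(self) -> None:
        # Cross-context reconstruction error of the optimal subspace model:
        # || (I - P_d) W_c ||_F with P_d the projector onto range(W_d).
        for c in range(len(self.maps)):
            for d in range(len(self.maps)):
                if c == d:
                    continue
                Q, _ = np.linalg.qr(self.maps[d])
                P = Q @ Q.T
                err = np.linalg.norm((np.eye(self.config.obs_dim) - P) @ self.maps[c])
                if err < self.config.min_separation:
                    raise ConfigurationError(
                        f"sensory contexts {c} and {d} share their subspace "
                        f"(cross error {err:.3f} < {self.config.min_separation})"
                    )

    def reset(self, seed: int | None = None) -> None:
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        self.context = 0
        self.t = 0

    @property
    def n_contexts(self) -> int:
        return self.config.n_contexts

    def step(self) -> tuple[np.ndarray, float, dict[str, Any]]:
        z = self.rng.standard_normal(self.config.latent_dim)
        obs = self.maps[self.context] @ z + self.config.noise * self.rng.standard_normal(
            self.config.obs_dim
        )
        self.t += 1
        info = {"context": self.context, "latent": z, "t": self.t}
        if self.t % self.config.switch_period == 0:
            self.context = (self.context + 1) % self.config.n_contexts
        return obs, 0.0, info


# --------------------------------------------------------------------------- #
# Isolated-activation (DecNef-style) probe
# --------------------------------------------------------------------------- #


@dataclass
class DecNefProbe:
    """Externally induce a pattern at one module's level.

    With ``clamp`` set, no coherent input is presented (the observation is
    zeroed): the targeted representation is strong but isolated, exactly the
    condition under which induced information should stay nonconscious.
    With ``clamp`` off and a full observation supplied, the probe degenerates
    to an ordinary settle-and-gate cycle.
    """

    target: ModuleId
    pattern: np.ndarray = field(default_factory=lambda: np.zeros(2))
    clamp: bool = True


def gate_cycle(
    grid: ModuleGrid,
    gate_config: GateConfig,
    observation: np.ndarray,
    n_iters: int = 2,
    inject: DecNefProbe | None = None,
) -> GateState:
    """One settle-and-gate cycle over all sensory modalities.

    ``observation`` may be a single frame or a short stimulus sequence (2-D
    array, one frame per row); with a sequence the gate runs on the
    root-mean-square mismatch across frames, the natural evidence
    accumulation for a stimulus that lasts longer than one frame.  The probe
    injection, if any, overrides the target's bottom-up representation on
    every frame (the top-down pass is re-run so the injection propagates);
    reward prediction errors are zero during a passive cycle.
    """
    frames = np.atleast_2d(np.asarray(observation, dtype=float))
    keys = [str(mid) for mid in grid.module_ids()]
    ordinals = np.array([mid.level.ordinal for mid in grid.module_ids()])
    if gate_config.include_levels is not None:
        sel = np.isin(ordinals, gate_config.include_levels)
        keys = [k for k, s in zip(keys, sel) if s]
        ordinals = ordinals[sel]

    sq_sum = np.zeros(len(keys))
    for frame in frames:
        for i in range(grid.n_modalities):
            for slot in grid.modality_slots(i):
                slot.board.clear()
            recurrent_settle(grid, frame, n_iters=n_iters, modality=i)
        if inject is not None:
            i = inject.target.modality
            k = inject.target.level.ordinal
            if i >= grid.n_modalities or k >= grid.n_levels:
                raise ConfigurationError(f"probe target {inject.target} is outside the grid")
            slots = grid.modality_slots(i)
            pattern = as_representation(inject.pattern, slots[k].board.dim, "probe pattern")
            slots[k].board.bottom_up = pattern
            # injection propagates top-down from the target modality's top estimate
            top = slots[-1].board.bottom_up
            sensory_generative_pass(grid, top, modality=i)
        mism = compute_mismatches(grid)
        sq_sum += np.array([mism[k] for k in keys]) ** 2
    m = np.sqrt(sq_sum / len(frames))
    return gate_step(
        keys, m, np.zeros_like(m), ordinals, gate_config, grid.n_levels, prior=None
    )


def run_decnef_probe(
    grid: ModuleGrid,
    gate_config: GateConfig,
    probe: DecNefProbe,
    observation: np.ndarray | None = None,
    n_iters: int = 2,
    n_frames: int = 5,
) -> GateState:
    """Execute one isolated-activation cycle and return the gate state.

    With the clamp on, the observation is zeroed: the target area receives
    its induced pattern but no related input from below or above.
    """
    if probe.target.modality >= grid.n_modalities or probe.target.level.ordinal >= grid.n_levels:
        raise ConfigurationError(f"probe target {probe.target} is outside the grid")
    if probe.clamp or observation is None:
        observation = np.zeros((n_frames, grid.config.raw_dim))
    return gate_cycle(grid, gate_config, observation, n_iters=n_iters, inject=probe)
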