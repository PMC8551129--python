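"""Per-module reinforcement learning.

Each (modality, level) module runs its own linear TD(0) critic over that
module's level-k representation, plus a softmax-preference actor over a small
discrete set of goal prototypes.  Every module computes its reward prediction
error delta on every step ("simultaneously and in parallel"); the
responsibility signal gates how strongly each module's parameters move.
Continuous control is delegated to the motor inverse models — RL only selects
among goal/command prototypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.special import softmax

from .core import ParameterError, ShapeError, StateError


def _features(s: np.ndarray, dim: int, kind: str = "linear") -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (dim,):
        raise ShapeError(f"representation has shape {s.shape}, expected ({dim},)")
    if kind == "quadratic":
        # [s, ||s||^2, 1] spans squared-distance rewards exactly
        return np.concatenate([s, [s @ s, 1.0]])
    return np.concatenate([s, [1.0]])


@dataclass
class RLModule:
    """Linear value function + preference actor for one module."""

    value_w: np.ndarray
    prefs: np.ndarray
    gamma: float
    delta: float = 0.0
    feature_kind: str = "linear"

    @classmethod
    def create(
        cls, rep_dim: int, n_actions: int, gamma: float = 0.9, feature_kind: str = "linear"
    ) -> "RLModule":
        if not (0.0 <= gamma < 1.0):
            raise ParameterError(f"gamma must be in [0, 1), got {gamma}")
        extra = 2 if feature_kind == "quadratic" else 1
        return cls(np.zeros(rep_dim + extra), np.zeros(n_actions), gamma, feature_kind=feature_kind)

    @property
    def rep_dim(self) -> int:
        extra = 2 if self.feature_kind == "quadratic" else 1
        return self.value_w.shape[0] - extra

    def features(self, s: np.ndarray) -> np.ndarray:
        return _features(s, self.rep_dim, self.feature_kind)

    def value(self, s: np.ndarray) -> float:
        return float(self.value_w @ self.features(s))

    def policy(self) -> np.ndarray:
        return softmax(self.prefs)

    def state_dict(self) -> dict[str, Any]:
        return {
            "value_w": self.value_w.tolist(),
            "prefs": self.prefs.tolist(),
            "gamma": self.gamma,
            "delta": self.delta,
            "feature_kind": self.feature_kind,
        }

    def load_state_dict(self, state: Mapping[str, Any]) -> None:
        self.value_w = np.asarray(state["value_w"], dtype=float)
        self.prefs = np.asarray(state["prefs"], dtype=float)
        self.gamma = float(state["gamma"])
        self.delta = float(state["delta"])
        self.feature_kind = str(state.get("feature_kind", "linear"))


def td_error(
    module: RLModule,
    s: np.ndarray,
    reward: float,
    s_next: np.ndarray,
    terminal: bool = False,
) -> float:
    """Reward prediction error: the difference between the predicted reward
    under this module's representation and the actual outcome,

        delta = r + gamma * V(s') * (1 - terminal) - V(s).
    """
    v_next = 0.0 if terminal else module.value(s_next)
    delta = reward + module.gamma * v_next - module.value(s)
    module.delta = float(delta)
    return module.delta


def gated_rl_update(
    module: RLModule,
    delta: float,
    responsibility: float,
    lr: float,
    s: np.ndarray,
    action: int | None = None,
    lr_policy: float | None = None,
    normalized: bool = False,
) -> RLModule:
    """TD(0) value step and preference (policy-gradient-style) step, both
    scaled by ``responsibility * lr``; zero responsibility changes nothing."""
    if not (0.0 <= responsibility <= 1.0):
        raise ParameterError(f"responsibility must be in [0, 1], got {responsibility}")
    if responsibility == 0.0:
        return module
    phi = module.features(s)
    if normalized:
        lr = lr / (1.0 + float(phi @ phi))
    module.value_w = module.value_w + responsibility * lr * delta * phi
    if action is not None:
        lp = lr if lr_policy is None else lr_policy
        pi = module.policy()
        grad = -pi
        grad[action] += 1.0
        module.prefs = module.prefs + responsibility * lp * delta * grad
    return module


def select_action(
    policies: Sequence[np.ndarray],
    responsibilities: np.ndarray,
    rng: np.random.Generator,
    mode: str = "blend",
) -> tuple[int, int]:
    """Pick an action from the responsibility-weighted mixture of per-module
    policies (``blend``) or from the single highest-responsibility module
    (``argmax``).  Returns (action, module index); deterministic given rng.
    """
    if len(policies) == 0:
        raise StateError("no module policies to select from")
    lam = np.asarray(responsibilities, dtype=float)
    if lam.shape != (len(policies),) or np.any(lam < -1e-12) or abs(lam.sum() - 1.0) > 1e-6:
        raise ParameterError("responsibilities must be a simplex over the module set")
    if mode == "blend":
        idx = int(rng.choice(len(policies), p=lam / lam.sum()))
    elif mode == "argmax":
        idx = int(np.argmax(lam))
    else:
        raise ParameterError(f"unknown selection mode {mode!r}")
    pi = softmax(np.asarray(policies[idx], dtype=float))
    action = int(rng.choice(len(pi), p=pi))
    return action, idx


def chain_value_closed_form(P: np.ndarray, r: np.ndarray, gamma: float) -> np.ndarray:
    """Exact value function of a fixed policy on a finite chain:
    V = (I - gamma P)^-1 r, with P the policy-induced transition matrix and
    r the expected one-step reward per state."""
    n = P.shape[0]
    return np.linalg.solve(np.eye(n) - gamma * P, r)
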