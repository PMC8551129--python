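"""Conjugate forward/inverse model pairs and their hierarchy passes.

Every module holds a *pair*: a forward/generative model ``g`` and an
inverse/inference model ``f`` of the same object.  In the sensory stream,
``f`` runs bottom-up (raw representation -> abstract representation) and
``g`` runs top-down (abstract -> raw): the generative map of the rawer
representation.  In the motor stream the directions are reversed: the
inverse model is the controller mapping a desired state to a command (which
*is* the desired state of the level below), and the forward model predicts
the achieved state from the lower-level state estimate and the command.

When a pair is perfectly matched to the world, the cascade of the generative
model and its inverse is an identity function, so the mismatch between the
pair's two estimates is zero.  That mismatch — the Euclidean norm of the
difference between the top-down and bottom-up estimates (sensory), or
between the desired and the predicted state (motor) — is the per-module
consistency signal consumed by the gating network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from .core import (
    GridConfig,
    ModuleGrid,
    ParameterError,
    ShapeError,
    SignalBoard,
    StateError,
    as_representation,
)

# --------------------------------------------------------------------------- #
# Trainable maps
# --------------------------------------------------------------------------- #


class AffineMap:
    """y = W z + b with plain SGD on squared error."""

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = np.asarray(W, dtype=float)
        self.b = np.asarray(b, dtype=float)

    @classmethod
    def create(cls, in_dim: int, out_dim: int, rng: np.random.Generator, scale: float = 0.1) -> "AffineMap":
        return cls(scale * rng.standard_normal((out_dim, in_dim)), np.zeros(out_dim))

    @classmethod
    def identity_block(cls, in_dim: int, out_dim: int, offset: int = 0) -> "AffineMap":
        """W selects the ``out_dim`` input coordinates starting at ``offset``."""
        W = np.zeros((out_dim, in_dim))
        W[:, offset : offset + out_dim] = np.eye(out_dim)
        return cls(W, np.zeros(out_dim))

    @property
    def in_dim(self) -> int:
        return self.W.shape[1]

    @property
    def out_dim(self) -> int:
        return self.W.shape[0]

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.shape != (self.in_dim,):
            raise ShapeError(f"affine map expects input of shape ({self.in_dim},), got {z.shape}")
        return self.W @ z + self.b

    def backward(self, z: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients into scratch and return dL/dz."""
        self._gW = np.outer(grad_out, z)
        self._gb = grad_out
        return self.W.T @ grad_out

    def apply_grads(self, lr: float) -> None:
        self.W -= lr * self._gW
        self.b -= lr * self._gb

    def sgd_step(self, z: np.ndarray, target: np.ndarray, lr: float, normalized: bool = False) -> float:
        """One gradient step on 0.5 * ||y - target||^2; returns pre-step error.

        With ``normalized`` the step is divided by 1 + ||z||^2 (normalized
        LMS), which keeps online closed-loop learning stable for any input
        magnitude.
        """
        y = self(z)
        g = y - target
        if normalized:
            lr = lr / (1.0 + float(z @ z))
        self.W -= lr * np.outer(g, z)
        self.b -= lr * g
        return float(np.linalg.norm(g))

    def state_dict(self) -> dict[str, Any]:
        return {"kind": "affine", "W": self.W.tolist(), "b": self.b.tolist()}

    def load_state_dict(self, state: Mapping[str, Any]) -> None:
        self.W = np.asarray(state["W"], dtype=float)
        self.b = np.asarray(state["b"], dtype=float)


class OneHiddenLayerMap:
    """y = W2 tanh(W1 z + b1) + b2; the smallest smooth nonlinear class."""

    def __init__(self, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray):
        self.W1 = np.asarray(W1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float)
        self.W2 = np.asarray(W2, dtype=float)
        self.b2 = np.asarray(b2, dtype=float)

    @classmethod
    def create(
        cls, in_dim: int, out_dim: int, rng: np.random.Generator, hidden: int = 16, scale: float = 0.1
    ) -> "OneHiddenLayerMap":
        return cls(
            scale * rng.standard_normal((hidden, in_dim)),
            np.zeros(hidden),
            scale * rng.standard_normal((out_dim, hidden)),
            np.zeros(out_dim),
        )

    @property
    def in_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def out_dim(self) -> int:
        return self.W2.shape[0]

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.shape != (self.in_dim,):
            raise ShapeError(f"map expects input of shape ({self.in_dim},), got {z.shape}")
        self._h = np.tanh(self.W1 @ z + self.b1)
        return self.W2 @ self._h + self.b2

    def backward(self, z: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        h = np.tanh(self.W1 @ z + self.b1)
        self._gW2 = np.outer(grad_out, h)
        self._gb2 = grad_out
        gh = (self.W2.T @ grad_out) * (1.0 - h * h)
        self._gW1 = np.outer(gh, z)
        self._gb1 = gh
        return self.W1.T @ gh

    def apply_grads(self, lr: float) -> None:
        self.W1 -= lr * self._gW1
        self.b1 -= lr * self._gb1
        self.W2 -= lr * self._gW2
        self.b2 -= lr * self._gb2

    def sgd_step(self, z: np.ndarray, target: np.ndarray, lr: float, normalized: bool = False) -> float:
        y = self(z)
        g = y - target
        if normalized:
            lr = lr / (1.0 + float(z @ z))
        self.backward(z, g)
        self.apply_grads(lr)
        return float(np.linalg.norm(g))

    def state_dict(self) -> dict[str, Any]:
        return {
            "kind": "mlp",
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
        }

    def load_state_dict(self, state: Mapping[str, Any]) -> None:
        self.W1 = np.asarray(state["W1"], dtype=float)
        self.b1 = np.asarray(state["b1"], dtype=float)
        self.W2 = np.asarray(state["W2"], dtype=float)
        self.b2 = np.asarray(state["b2"], dtype=float)


def make_map(
    model_class: str,
    in_dim: int,
    out_dim: int,
    rng: np.random.Generator,
    scale: float = 0.1,
    hidden: int = 16,
):
    if model_class == "affine":
        return AffineMap.create(in_dim, out_dim, rng, scale=scale)
    if model_class == "mlp":
        return OneHiddenLayerMap.create(in_dim, out_dim, rng, hidden=hidden, scale=scale)
    raise ParameterError(f"unknown model class {model_class!r}")


# --------------------------------------------------------------------------- #
# Conjugate pair
# --------------------------------------------------------------------------- #


@dataclass
class ConjugatePair:
    """Forward/generative model ``g`` and inverse/inference model ``f``.

    Input conventions per level k (lower = level k-1, raw input at level -1):

    sensory:  f : concat(x_{k-1}, x_hat_{k-1}) -> x_k
              g : concat(x_k, x_hat_k)         -> x_hat_{k-1}
    motor:    f : concat(x_d_k, x_hat_k, x_hat_{k-1}) -> u_k  (= x_d_{k-1})
              g : concat(x_hat_{k-1}, u_k)            -> x_hat_k
    """

    forward: Any  # g
    inverse: Any  # f
    stream: str
    level: int

    def state_dict(self) -> dict[str, Any]:
        return {
            "stream": self.stream,
            "level": self.level,
            "forward": self.forward.state_dict(),
            "inverse": self.inverse.state_dict(),
        }

    def load_state_dict(self, state: Mapping[str, Any]) -> None:
        self.forward.load_state_dict(state["forward"])
        self.inverse.load_state_dict(state["inverse"])


def build_pair(config: GridConfig, stream: str, level: int, rng: np.random.Generator) -> ConjugatePair:
    """Build the conjugate pair for one (stream, level) with config-set dims."""
    dims = config.level_dims
    d_k = dims[level]
    d_low = dims[level - 1] if level > 0 else config.raw_dim
    u_dim = d_low if level > 0 else config.u_dim
    kw = dict(scale=config.init_scale, hidden=config.hidden_units)
    if stream == "sensory":
        f = make_map(config.model_class, 2 * d_low if level > 0 else d_low + d_k, d_k, rng, **kw)
        g = make_map(config.model_class, 2 * d_k, d_low, rng, **kw)
    else:
        f = make_map(config.model_class, d_k + d_k + d_low, u_dim, rng, **kw)
        g = make_map(config.model_class, d_low + u_dim, d_k, rng, **kw)
    return ConjugatePair(forward=g, inverse=f, stream=stream, level=level)


# --------------------------------------------------------------------------- #
# Sensory passes
# --------------------------------------------------------------------------- #


def _topdown_or_zero(board: SignalBoard) -> np.ndarray:
    # first-step bootstrap: top-down estimates start at zero
    return board.top_down if board.top_down is not None else np.zeros(board.dim)


def sensory_inference_pass(
    grid: ModuleGrid, observation: np.ndarray, modality: int = 0
) -> list[SignalBoard]:
    """One upward sweep: bottom-up x at every level from the raw observation.

    Each inverse model also receives the previous step's top-down estimate at
    its input level (zero vectors before the first generative pass).
    """
    observation = as_representation(observation, grid.config.raw_dim, "observation")
    slots = grid.modality_slots(modality)
    slots[0].board.raw_input = observation
    below = observation
    below_hat = _topdown_or_zero(slots[0].board)  # level-0 f pairs obs with its own x_hat
    for k, slot in enumerate(slots):
        if k == 0:
            z = np.concatenate([below, below_hat])
        else:
            prev = slots[k - 1].board
            z = np.concatenate([prev.bottom_up, _topdown_or_zero(prev)])
        slot.board.f_in_cache = z  # exact input, for train/measure consistency
        slot.board.bottom_up = slot.pair.inverse(z)
    return [s.board for s in slots]


def sensory_generative_pass(
    grid: ModuleGrid, top_state: np.ndarray, modality: int = 0
) -> list[SignalBoard]:
    """One downward sweep: top-down x_hat at every level from the top state."""
    slots = grid.modality_slots(modality)
    top = slots[-1].board
    top.top_down = as_representation(top_state, top.dim, "top_state")
    for k in range(grid.n_levels - 1, -1, -1):
        slot = slots[k]
        z = np.concatenate([_bu_or_zero(slot.board), slot.board.top_down])
        out = slot.pair.forward(z)
        if k > 0:
            slots[k - 1].board.top_down = out
        else:
            slot.board.reconstruction = out
    return [s.board for s in slots]


def _bu_or_zero(board: SignalBoard) -> np.ndarray:
    return board.bottom_up if board.bottom_up is not None else np.zeros(board.dim)


def recurrent_settle(
    grid: ModuleGrid, observation: np.ndarray, n_iters: int = 3, modality: int = 0
) -> list[SignalBoard]:
    """Alternate inference and generative passes ``n_iters`` times.

    The generative pass is re-anchored at the current top bottom-up estimate,
    so with matched pairs the mismatch is non-increasing on noiseless input.
    """
    if n_iters < 1:
        raise ParameterError(f"n_iters must be >= 1, got {n_iters}")
    boards: list[SignalBoard] = []
    for _ in range(n_iters):
        sensory_inference_pass(grid, observation, modality)
        top = grid.modality_slots(modality)[-1].board.bottom_up
        boards = sensory_generative_pass(grid, top, modality)
    return boards


# --------------------------------------------------------------------------- #
# Motor passes
# --------------------------------------------------------------------------- #


def motor_topdown_pass(grid: ModuleGrid, goal: np.ndarray, modality: int = 0) -> list[SignalBoard]:
    """Downward control sweep: commands from the abstract goal to the plant.

    u_k = f_k(x_d_k, x_hat_k, x_hat_{k-1}); the command at level k becomes the
    desired state at level k-1, bottoming out in the command applied to the
    environment (stored on the level-0 board).
    """
    slots = grid.modality_slots(modality)
    top = slots[-1].board
    top.desired = as_representation(goal, top.dim, "goal")
    state = grid.state_estimate(modality)
    for k in range(grid.n_levels - 1, -1, -1):
        slot = slots[k]
        if slot.board.top_down is None:
            raise StateError(
                "motor top-down pass needs forward-state estimates; "
                "run motor_bottomup_pass or prime_motor first"
            )
        below_hat = slots[k - 1].board.top_down if k > 0 else state
        if below_hat is None:
            raise StateError("missing lower-level state estimate; prime_motor first")
        z = np.concatenate([slot.board.desired, slot.board.top_down, below_hat])
        u = slot.pair.inverse(z)
        slot.board.command = u
        if k > 0:
            slots[k - 1].board.desired = u
    return [s.board for s in slots]


def motor_bottomup_pass(
    grid: ModuleGrid, state_estimate: np.ndarray, modality: int = 0
) -> list[SignalBoard]:
    """Upward prediction sweep: x_hat_k = g_k(x_hat_{k-1}, u_k).

    Grounded at the sensed raw state; requires commands from a prior
    top-down pass.
    """
    state_estimate = as_representation(state_estimate, grid.config.raw_dim, "state_estimate")
    grid._state_estimate[modality] = state_estimate
    slots = grid.modality_slots(modality)
    below_hat = state_estimate
    for slot in slots:
        if slot.board.command is None:
            raise StateError("motor bottom-up pass needs commands; run motor_topdown_pass first")
        z = np.concatenate([below_hat, slot.board.command])
        slot.board.top_down = slot.pair.forward(z)
        below_hat = slot.board.top_down
    return [s.board for s in slots]


# --------------------------------------------------------------------------- #
# Mismatches
# --------------------------------------------------------------------------- #


def compute_mismatches(grid: ModuleGrid, modality: int | None = None) -> dict[str, float]:
    """Per-module conjugate-pair mismatch (Euclidean norm of the difference
    between the pair's two estimates).

    sensory pair at level k: || x_hat_{k-1} - x_{k-1} || at its lower
    interface (level 0 compares the reconstruction against the raw bottom-up
    estimate); motor pair at level k: || x_d_k - x_hat_k ||.
    """
    out: dict[str, float] = {}
    modalities = range(grid.n_modalities) if modality is None else [modality]
    for i in modalities:
        slots = grid.modality_slots(i)
        stream = grid.config.stream_of(i)
        for k, slot in enumerate(slots):
            b = slot.board
            if stream == "sensory":
                if k == 0:
                    a, c = b.reconstruction, b.raw_input
                else:
                    low = slots[k - 1].board
                    a, c = low.top_down, low.bottom_up
            else:
                a, c = b.desired, b.top_down
            if a is None or c is None:
                raise StateError(
                    f"mismatch for module {slot.module_id} needs both estimates populated"
                )
            if a.shape != c.shape:
                raise ShapeError(f"estimate dims differ for module {slot.module_id}")
            out[str(slot.module_id)] = float(np.linalg.norm(a - c))
    return out


def mismatch_norm(estimate_a: np.ndarray, estimate_b: np.ndarray) -> float:
    """Euclidean mismatch between two same-level estimates."""
    a = np.asarray(estimate_a, dtype=float)
    b = np.asarray(estimate_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"estimates have different shapes {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


# --------------------------------------------------------------------------- #
# Responsibility-gated learning
# --------------------------------------------------------------------------- #


def gated_pair_update(
    pair: ConjugatePair,
    f_in: np.ndarray,
    target: np.ndarray,
    responsibility: float,
    lr: float,
    g_pre: np.ndarray | None = None,
    g_post: np.ndarray | None = None,
) -> ConjugatePair:
    """One gradient step on the squared pair mismatch for both f and g.

    The loss is the squared residual of the pair composition
    ``|| target - g(concat(g_pre, f(f_in), g_post)) ||^2`` — the cascade of
    the inverse and generative models should be an identity, and the gradient
    flows through both.  The effective step size is ``lr * responsibility``:
    a zero responsibility leaves the parameters bit-identical (the gate
    multiplies the learning rate; it never masks which data a module sees).
    """
    if not (0.0 <= responsibility <= 1.0):
        raise ParameterError(f"responsibility must be in [0, 1], got {responsibility}")
    if lr <= 0:
        raise ParameterError(f"learning rate must be positive, got {lr}")
    if responsibility == 0.0:
        return pair
    f_in = np.asarray(f_in, dtype=float)
    target = np.asarray(target, dtype=float)
    pre = np.asarray(g_pre, dtype=float) if g_pre is not None else np.empty(0)
    post = np.asarray(g_post, dtype=float) if g_post is not None else np.empty(0)

    y = pair.inverse(f_in)
    g_in = np.concatenate([pre, y, post])
    recon = pair.forward(g_in)
    grad_out = recon - target
    grad_gin = pair.forward.backward(g_in, grad_out)
    grad_y = grad_gin[len(pre) : len(pre) + len(y)]
    pair.inverse.backward(f_in, grad_y)
    eff = lr * responsibility
    pair.forward.apply_grads(eff)
    pair.inverse.apply_grads(eff)
    return pair
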