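"""Shared domain types: hierarchy addressing, signal boards, grid construction,
seed fan-out, and run logging.

The architecture is a grid of modules indexed by (modality ``i``, level ``k``).
Each module owns a conjugate forward/inverse model pair, a small reinforcement
learning component, and a signal board holding the current bottom-up estimate
``x``, top-down estimate ``x_hat`` and, in the motor stream, the desired state
``x_d`` and command ``u``.  Level 0 is the rawest representation (closest to
sensors and muscles); the top level is the most abstract.  Representation
dimension never increases with level: abstraction reduces dimension.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field


# --------------------------------------------------------------------------- #
# Errors
# --------------------------------------------------------------------------- #

class ConfigurationError(ValueError):
    """Invalid grid/experiment configuration (rejected before any stepping)."""


class ShapeError(ValueError):
    """Representation dimension does not match the configured level dimension."""


class ParameterError(ValueError):
    """A scalar hyperparameter is outside its admissible range."""


class StateError(RuntimeError):
    """An operation was invoked before the signals it needs were populated."""


class SignalValidationError(ValueError):
    """A signal value failed validation (non-finite, non-simplex, ...)."""


# --------------------------------------------------------------------------- #
# Hierarchy addressing
# --------------------------------------------------------------------------- #

_LEVEL_LABELS = {
    2: ["L", "H"],
    3: ["LL", "L", "H"],
    4: ["LL", "L", "H", "HH"],
}


def level_labels(n_levels: int) -> list[str]:
    """Conventional labels for a hierarchy of ``n_levels`` levels.

    Four levels get the classic LL/L/H/HH naming (one-lower-than-lower up to
    higher-than-higher); other depths fall back to ``L0``..``L{K-1}``.
    """
    if n_levels in _LEVEL_LABELS:
        return list(_LEVEL_LABELS[n_levels])
    return [f"L{k}" for k in range(n_levels)]


@dataclass(frozen=True, order=True)
class LevelIndex:
    """Position in the hierarchy; ordinal 0 is rawest, K-1 most abstract."""

    ordinal: int
    label: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.ordinal < 0:
            raise ConfigurationError(f"level ordinal must be >= 0, got {self.ordinal}")


@dataclass(frozen=True, order=True)
class ModuleId:
    """(modality, level) address of one conjugate-pair module in the grid."""

    modality: int
    level: LevelIndex

    @property
    def key(self) -> tuple[int, int]:
        return (self.modality, self.level.ordinal)

    def __str__(self) -> str:  # used in log column names
        return f"m{self.modality}k{self.level.ordinal}"


def as_representation(values: Any, dim: int | None = None, name: str = "representation") -> np.ndarray:
    """Validate and coerce a 1-D finite float vector."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ShapeError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise SignalValidationError(f"{name} contains non-finite entries")
    if dim is not None and arr.shape[0] != dim:
        raise ShapeError(f"{name} has dimension {arr.shape[0]}, expected {dim}")
    return arr


@dataclass
class SignalBoard:
    """Per-module signals for the current step.

    ``bottom_up`` (x) and ``top_down`` (x_hat) always share the level
    dimension.  ``desired`` (x_d) and ``command`` (u) are motor-stream only;
    the command issued at level k is the desired state handed to level k-1.
    """

    dim: int
    bottom_up: np.ndarray | None = None
    top_down: np.ndarray | None = None
    desired: np.ndarray | None = None
    command: np.ndarray | None = None
    reconstruction: np.ndarray | None = None  # level-0 only: predicted raw input
    raw_input: np.ndarray | None = None  # level-0 only: the observation itself
    f_in_cache: np.ndarray | None = None  # exact input the inverse model consumed

    def clear(self) -> None:
        self.bottom_up = None
        self.top_down = None
        self.desired = None
        self.command = None
        self.reconstruction = None
        self.raw_input = None
        self.f_in_cache = None


# --------------------------------------------------------------------------- #
# Grid configuration and construction
# --------------------------------------------------------------------------- #

class GridConfig(BaseModel):
    """Configuration of the module grid.

    ``streams`` gives the stream of each modality ("sensory" or "motor"); a
    single string applies to all modalities.  ``level_dims`` is ordered from
    rawest (level 0) to most abstract and must be non-increasing.
    """

    n_modalities: int = 1
    level_dims: list[int] = Field(default_factory=lambda: [8, 6, 4, 2])
    streams: str | list[str] = "sensory"
    model_class: str = "affine"  # "affine" | "mlp"
    hidden_units: int = 16
    init_scale: float = 0.1
    input_dim: int | None = None  # raw input dim (observation / plant state); default level_dims[0]
    command_dim: int | None = None  # motor stream; default level_dims[0]
    n_actions: int = 3
    gamma: float = 0.9
    value_features: str = "linear"  # "linear" | "quadratic"
    seed: int = 0

    def stream_of(self, modality: int) -> str:
        if isinstance(self.streams, str):
            return self.streams
        return self.streams[modality]

    @property
    def raw_dim(self) -> int:
        return self.input_dim if self.input_dim is not None else self.level_dims[0]

    @property
    def u_dim(self) -> int:
        return self.command_dim if self.command_dim is not None else self.level_dims[0]


@dataclass
class ModuleSlot:
    """Everything one (i, k) module owns."""

    module_id: ModuleId
    pair: Any  # ConjugatePair
    rl: Any  # RLModule
    board: SignalBoard


class ModuleGrid:
    """The full parallel/hierarchical grid of modules.

    Construction is a pure function of (config, seed): two builds with equal
    inputs are parameter-identical.
    """

    def __init__(self, config: GridConfig, slots: dict[ModuleId, ModuleSlot]):
        self.config = config
        self.slots = slots
        self.levels = [
            LevelIndex(k, lab) for k, lab in enumerate(level_labels(len(config.level_dims)))
        ]
        # per-modality scratch: last primed raw state (motor stream)
        self._state_estimate: dict[int, np.ndarray | None] = {
            i: None for i in range(config.n_modalities)
        }

    # -- addressing ---------------------------------------------------------
    @property
    def n_levels(self) -> int:
        return len(self.config.level_dims)

    @property
    def n_modalities(self) -> int:
        return self.config.n_modalities

    @property
    def n_modules(self) -> int:
        return len(self.slots)

    def module_ids(self) -> list[ModuleId]:
        return sorted(self.slots.keys())

    def slot(self, modality: int, level: int) -> ModuleSlot:
        return self.slots[ModuleId(modality, self.levels[level])]

    def modality_slots(self, modality: int) -> list[ModuleSlot]:
        return [self.slot(modality, k) for k in range(self.n_levels)]

    def __iter__(self) -> Iterator[ModuleSlot]:
        return (self.slots[mid] for mid in self.module_ids())

    # -- boards -------------------------------------------------------------
    def reset_boards(self) -> None:
        for slot in self:
            slot.board.clear()
        for i in self._state_estimate:
            self._state_estimate[i] = None

    def prime_motor(self, modality: int, state: np.ndarray) -> None:
        """Seed top-down estimates before the first bottom-up motor pass.

        The recurrence needs an initial condition: predicted states start at
        zero at every level and the raw state estimate is the sensed state.
        """
        state = as_representation(state, self.config.raw_dim, "state")
        self._state_estimate[modality] = state
        for slot in self.modality_slots(modality):
            if slot.board.top_down is None:
                slot.board.top_down = np.zeros(slot.board.dim)

    def state_estimate(self, modality: int) -> np.ndarray | None:
        return self._state_estimate[modality]

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"config": self.config.model_dump()}
        params: dict[str, Any] = {}
        for slot in self:
            params[str(slot.module_id)] = {
                "pair": slot.pair.state_dict(),
                "rl": slot.rl.state_dict(),
            }
        out["modules"] = params
        return out

    def load_state_dict(self, state: Mapping[str, Any]) -> None:
        for slot in self:
            entry = state["modules"][str(slot.module_id)]
            slot.pair.load_state_dict(entry["pair"])
            slot.rl.load_state_dict(entry["rl"])

    def save_checkpoint(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(), fh)

    def load_checkpoint(self, path: str) -> None:
        with open(path) as fh:
            self.load_state_dict(json.load(fh))


def child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one global seed out to ``n`` independent child generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def build_grid(config: GridConfig) -> ModuleGrid:
    """Construct the module grid: one conjugate pair, one RL component and one
    signal board per (modality, level).  Deterministic given ``config.seed``.
    """
    from .conjugate import build_pair  # local import avoids a module cycle
    from .rl import RLModule

    if config.n_modalities < 1:
        raise ConfigurationError("grid needs at least one modality")
    dims = config.level_dims
    if len(dims) < 2:
        raise ConfigurationError("grid needs at least two levels")
    if any(d < 1 for d in dims):
        raise ConfigurationError(f"level dimensions must be positive: {dims}")
    if any(dims[k + 1] > dims[k] for k in range(len(dims) - 1)):
        raise ConfigurationError(
            f"level dimensions must be non-increasing with abstraction: {dims}"
        )
    if not isinstance(config.streams, str) and len(config.streams) != config.n_modalities:
        raise ConfigurationError("streams list length must equal n_modalities")

    labels = level_labels(len(dims))
    rngs = iter(child_seeds(config.seed, config.n_modalities * len(dims)))
    slots: dict[ModuleId, ModuleSlot] = {}
    for i in range(config.n_modalities):
        stream = config.stream_of(i)
        if stream not in ("sensory", "motor"):
            raise ConfigurationError(f"unknown stream {stream!r}")
        for k, d in enumerate(dims):
            rng = next(rngs)
            mid = ModuleId(i, LevelIndex(k, labels[k]))
            pair = build_pair(config, stream, k, rng)
            rl = RLModule.create(
                rep_dim=d,
                n_actions=config.n_actions,
                gamma=config.gamma,
                feature_kind=config.value_features,
            )
            slots[mid] = ModuleSlot(mid, pair, rl, SignalBoard(dim=d))
    return ModuleGrid(config, slots)


# --------------------------------------------------------------------------- #
# Run logging
# --------------------------------------------------------------------------- #

@dataclass
class StepSnapshot:
    """One step of an experiment: scalar signals per module plus globals."""

    step: int
    seed: int
    true_context: int
    selected_module: str
    action: int
    reward: float
    entropy: float
    mismatch: dict[str, float]
    delta: dict[str, float]
    cog_error: dict[str, float]
    likelihood: dict[str, float]
    prior: dict[str, float]
    responsibility: dict[str, float]

    def validate(self) -> None:
        for name in ("reward", "entropy"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise SignalValidationError(f"non-finite value for {name!r}: {v}")
        for name in ("mismatch", "delta", "cog_error", "likelihood", "prior", "responsibility"):
            for mod, v in getattr(self, name).items():
                if not np.isfinite(v):
                    raise SignalValidationError(
                        f"non-finite value for {name!r} of module {mod}: {v}"
                    )


class RunLog:
    """Append-only per-step record of every gating and learning signal."""

    def __init__(self, seed: int):
        self.seed = seed
        self.records: list[StepSnapshot] = []

    def __len__(self) -> int:
        return len(self.records)

    def append(self, snapshot: StepSnapshot) -> None:
        snapshot.validate()
        self.records.append(snapshot)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, Any] = {
                "step": rec.step,
                "seed": rec.seed,
                "true_context": rec.true_context,
                "selected_module": rec.selected_module,
                "action": rec.action,
                "reward": rec.reward,
                "entropy": rec.entropy,
            }
            for name in ("mismatch", "delta", "cog_error", "likelihood", "prior", "responsibility"):
                for mod, v in getattr(rec, name).items():
                    row[f"{name}_{mod}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(dataclasses.asdict(rec)) + "\n")


def log_step(log: RunLog, snapshot: StepSnapshot) -> RunLog:
    """Append a validated snapshot; prior records are never modified."""
    log.append(snapshot)
    return log


def default_grid_config(seed: int = 0) -> GridConfig:
    """The default showcase grid: one sensory and one motor modality, four
    levels with dimensions 8/6/4/2 (LL, L, H, HH)."""
    return GridConfig(
        n_modalities=2,
        level_dims=[8, 6, 4, 2],
        streams=["sensory", "motor"],
        seed=seed,
    )
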