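"""The cognitive reality monitoring network (the gate).

From every module's conjugate-pair mismatch m_ik and reward prediction error
delta_ik, the gate computes

    cognitive prediction error   e_ik^2 = m_ik^2 + w * delta_ik^2
    likelihood                   L_ik   = exp(-e_ik^2 / sigma^2) / sum_lm exp(-e_lm^2 / sigma^2)
    responsibility               lam_ik propto prior_ik * L_ik   (high levels)
                                 lam_ik propto L_ik              (low levels)
    entropy                      S = -sum lam_ik ln lam_ik

A responsibility prior is predicted by a learned map ``h`` from abstract
high-level representations only — never from the error signals — and is
trained with the responsibility signal itself as the teaching signal.  Low
entropy (one dominant module) is the operational criterion for conscious
involvement; the argmax module is the object of metacognition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
from pydantic import BaseModel
from scipy.special import logsumexp

from .core import ParameterError, SignalValidationError, StateError


class DegenerateGateError(RuntimeError):
    """All prior-times-likelihood products vanished; the gate is undefined."""


class GateConfig(BaseModel):
    """Gate hyperparameters.

    sigma: softmax temperature (same units as the cognitive error).
    w: weight of the squared reward prediction error inside e_ik^2.
    level_prior_min: smallest level ordinal at which the learned prior
        multiplies the likelihood ("high levels of the hierarchy"); below it
        the responsibility equals the likelihood.
    entropy_threshold: consciousness criterion theta_S in nats; ``None``
        means 0.5 * ln(number of modules), resolved at readout time.
    renormalize: project prior*likelihood products back to the simplex so the
        entropy readout stays comparable across steps.
    include_levels: restrict gating to these level ordinals (None = all).
    """

    sigma: float = 1.0
    w: float = 1.0
    level_prior_min: int | None = None  # None -> top level only
    entropy_threshold: float | None = None
    renormalize: bool = True
    include_levels: list[int] | None = None

    def resolved_prior_min(self, n_levels: int) -> int:
        return n_levels - 1 if self.level_prior_min is None else self.level_prior_min

    def resolved_threshold(self, n_modules: int) -> float:
        if self.entropy_threshold is not None:
            return self.entropy_threshold
        return 0.5 * np.log(n_modules)


@dataclass
class GateState:
    """All gate signals for one step, aligned over ``module_keys``."""

    module_keys: list[str]
    e: np.ndarray
    likelihood: np.ndarray
    prior: np.ndarray
    responsibility: np.ndarray
    entropy: float

    def as_dicts(self) -> dict[str, dict[str, float]]:
        return {
            name: dict(zip(self.module_keys, np.asarray(getattr(self, attr), dtype=float)))
            for name, attr in (
                ("e", "e"),
                ("likelihood", "likelihood"),
                ("prior", "prior"),
                ("responsibility", "responsibility"),
            )
        }


@dataclass
class MetacognitionReport:
    conscious: bool
    object_of_metacognition: str
    entropy: float
    responsibility: dict[str, float]


# --------------------------------------------------------------------------- #
# Gate math
# --------------------------------------------------------------------------- #


def cognitive_error(mismatch: np.ndarray, delta: np.ndarray, w: float) -> np.ndarray:
    """e_ik = sqrt(m_ik^2 + w * delta_ik^2) per module; w = 0 reduces to
    mismatch-only gating."""
    if w < 0:
        raise ParameterError(f"reward-error weight w must be >= 0, got {w}")
    m = np.asarray(mismatch, dtype=float)
    d = np.asarray(delta, dtype=float)
    if m.shape != d.shape:
        raise ParameterError("mismatch and delta vectors must align")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(d))):
        raise SignalValidationError("non-finite input to cognitive_error")
    return np.sqrt(m * m + w * d * d)


def likelihoods(e: np.ndarray, sigma: float) -> np.ndarray:
    """Softmax of the negated squared cognitive errors, L_ik sums to one.
    Computed with max-subtraction so enormous errors underflow gracefully."""
    if sigma <= 0:
        raise ParameterError(f"temperature sigma must be > 0, got {sigma}")
    e = np.asarray(e, dtype=float)
    logits = -(e * e) / (sigma * sigma)
    p = np.exp(logits - logits.max())
    return p / p.sum()


def _check_simplex(p: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-12) or not np.isfinite(p).all() or abs(p.sum() - 1.0) > tol:
        raise SignalValidationError(f"{name} is not a probability simplex: {p}")
    return np.clip(p, 0.0, None)


def responsibilities(
    likelihood: np.ndarray,
    prior: np.ndarray,
    high_level_mask: np.ndarray,
    renormalize: bool = True,
) -> np.ndarray:
    """Responsibility signal: prior-weighted likelihood at high levels,
    plain likelihood below, renormalized to the simplex.

    ``high_level_mask`` marks the modules whose level ordinal is at or above
    the configured prior cutoff.
    """
    L = _check_simplex(likelihood, "likelihood")
    lam_hat = _check_simplex(prior, "prior")
    mask = np.asarray(high_level_mask, dtype=bool)
    if mask.shape != L.shape:
        raise ParameterError("high_level_mask must align with the module set")
    # scale the prior to mean one over the masked modules, so an
    # uninformative (uniform) prior is exactly neutral even when it applies
    # to only part of the module set; only relative prior weight matters
    masked_mean = lam_hat[mask].mean() if mask.any() else 1.0
    weight = lam_hat / masked_mean if masked_mean > 0.0 else np.zeros_like(lam_hat)
    lam = np.where(mask, weight * L, L)
    total = lam.sum()
    if total <= 0.0:
        raise DegenerateGateError(
            "all prior-times-likelihood products are zero; gate is degenerate"
        )
    return lam / total if renormalize else lam


def entropy(lam: np.ndarray) -> float:
    """S = -sum lam ln lam in nats, with 0 ln 0 := 0; 0 <= S <= ln N."""
    lam = _check_simplex(lam, "responsibility")
    nz = lam[lam > 0.0]
    return float(-np.sum(nz * np.log(nz)))


def readout(state: GateState, entropy_threshold: float) -> MetacognitionReport:
    """Consciousness criterion S <= theta_S; the object of metacognition is
    the argmax-responsibility module (lowest index on ties)."""
    lam = np.asarray(state.responsibility, dtype=float)
    obj = state.module_keys[int(np.argmax(lam))]  # argmax takes first on ties
    return MetacognitionReport(
        conscious=bool(state.entropy <= entropy_threshold),
        object_of_metacognition=obj,
        entropy=state.entropy,
        responsibility=dict(zip(state.module_keys, lam)),
    )


# --------------------------------------------------------------------------- #
# Responsibility prior
# --------------------------------------------------------------------------- #


class PriorEstimator:
    """Affine-plus-softmax map ``h`` from concatenated high-level
    representations to a simplex over modules.

    Zero-initialized, so an untrained estimator outputs the uniform simplex.
    It never sees cognitive error signals: its inputs are abstract
    representations only, and its teaching signal is the responsibility
    vector itself (gated cross-entropy).
    """

    def __init__(self, in_dim: int, n_modules: int):
        self.W = np.zeros((n_modules, in_dim))
        self.b = np.zeros(n_modules)

    @property
    def n_modules(self) -> int:
        return self.W.shape[0]

    def predict(self, signals: np.ndarray) -> np.ndarray:
        z = np.asarray(signals, dtype=float)
        if z.shape != (self.W.shape[1],):
            raise StateError(
                f"prior estimator expects high-level signals of dim {self.W.shape[1]}, got {z.shape}"
            )
        logits = self.W @ z + self.b
        return np.exp(logits - logsumexp(logits))

    def update(self, signals: np.ndarray, target: np.ndarray, lr: float) -> "PriorEstimator":
        """One cross-entropy gradient step toward ``target`` (a simplex)."""
        target = _check_simplex(target, "prior target")
        if lr == 0.0:
            return self
        z = np.asarray(signals, dtype=float)
        p = self.predict(z)
        grad = p - target  # d CE / d logits
        self.W -= lr * np.outer(grad, z)
        self.b -= lr * grad
        return self

    def state_dict(self) -> dict[str, Any]:
        return {"W": self.W.tolist(), "b": self.b.tolist()}

    def load_state_dict(self, state: Mapping[str, Any]) -> None:
        self.W = np.asarray(state["W"], dtype=float)
        self.b = np.asarray(state["b"], dtype=float)


def prior_predict(h: PriorEstimator, high_level_signals: np.ndarray) -> np.ndarray:
    return h.predict(high_level_signals)


def prior_update(
    h: PriorEstimator, high_level_signals: np.ndarray, target: np.ndarray, lr: float
) -> PriorEstimator:
    return h.update(high_level_signals, target, lr)


# --------------------------------------------------------------------------- #
# One full gate step
# --------------------------------------------------------------------------- #


def gate_step(
    module_keys: Sequence[str],
    mismatch: np.ndarray,
    delta: np.ndarray,
    level_ordinals: np.ndarray,
    config: GateConfig,
    n_levels: int,
    prior: np.ndarray | None = None,
) -> GateState:
    """Compute e, L, lambda and S for the module set in one call.

    ``prior`` defaults to uniform (equivalent to no prior information).
    """
    keys = list(module_keys)
    e = cognitive_error(mismatch, delta, config.w)
    L = likelihoods(e, config.sigma)
    if prior is None:
        prior = np.full(len(keys), 1.0 / len(keys))
    mask = np.asarray(level_ordinals) >= config.resolved_prior_min(n_levels)
    lam = responsibilities(L, prior, mask, renormalize=config.renormalize)
    S = entropy(lam) if config.renormalize else float("nan")
    return GateState(
        module_keys=keys,
        e=e,
        likelihood=L,
        prior=np.asarray(prior, dtype=float),
        responsibility=lam,
        entropy=S if config.renormalize else _entropy_unnormalized(lam),
    )


def _entropy_unnormalized(lam: np.ndarray) -> float:
    # sensitivity mode: entropy of the normalized shadow of an unnormalized lam
    lam = np.asarray(lam, dtype=float)
    total = lam.sum()
    if total <= 0:
        raise DegenerateGateError("cannot take entropy of an all-zero responsibility vector")
    return entropy(lam / total)
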