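"""Shared fixtures and construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from crmn.core import GridConfig, build_grid
from crmn.conjugate import AffineMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sensory_grid(dims, n_modalities=1, input_dim=None, seed=0, init_scale=0.1):
    cfg = GridConfig(
        n_modalities=n_modalities,
        level_dims=list(dims),
        streams="sensory",
        input_dim=input_dim,
        init_scale=init_scale,
        seed=seed,
    )
    return build_grid(cfg)


def motor_grid(dims, n_modalities=1, input_dim=None, command_dim=None, seed=0, init_scale=0.1):
    cfg = GridConfig(
        n_modalities=n_modalities,
        level_dims=list(dims),
        streams="motor",
        input_dim=input_dim,
        command_dim=command_dim,
        init_scale=init_scale,
        seed=seed,
    )
    return build_grid(cfg)


def set_identity_sensory(grid, modality=0):
    """Make every f and g pass its first input block through unchanged.

    Requires square level dims (all equal to the raw input dimension).
    """
    for slot in grid.modality_slots(modality):
        f, g = slot.pair.inverse, slot.pair.forward
        slot.pair.inverse = AffineMap.identity_block(f.in_dim, f.out_dim)
        slot.pair.forward = AffineMap.identity_block(g.in_dim, g.out_dim)
    return grid


def set_matched_sensory(grid, rng, modality=0):
    """Install an exactly invertible pair per level: f projects with an
    orthonormal frame D^T and g reconstructs with D (ignoring the recurrent
    top-down input block).  Data drawn from g's own generative map is then
    recovered exactly, so the pair mismatch is zero."""
    import numpy as np

    dims = grid.config.level_dims
    frames = []
    for k, slot in enumerate(grid.modality_slots(modality)):
        d_low = dims[k - 1] if k > 0 else grid.config.raw_dim
        d_k = dims[k]
        D = np.linalg.qr(rng.standard_normal((d_low, d_k)))[0]
        frames.append(D)
        f, g = slot.pair.inverse, slot.pair.forward
        Wf = np.zeros((d_k, f.in_dim))
        Wf[:, :d_low] = D.T
        slot.pair.inverse = AffineMap(Wf, np.zeros(d_k))
        Wg = np.zeros((d_low, g.in_dim))
        Wg[:, :d_k] = D
        slot.pair.forward = AffineMap(Wg, np.zeros(d_low))
    return frames
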