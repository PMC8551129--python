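"""Conjugate-pair passes, mismatches, and responsibility-gated learning."""

import json

import numpy as np
import pytest

from crmn.conjugate import (
    AffineMap,
    OneHiddenLayerMap,
    compute_mismatches,
    gated_pair_update,
    mismatch_norm,
    motor_bottomup_pass,
    motor_topdown_pass,
    recurrent_settle,
    sensory_generative_pass,
    sensory_inference_pass,
)
from crmn.core import ParameterError, ShapeError, StateError

from conftest import motor_grid, sensory_grid, set_identity_sensory, set_matched_sensory


class TestSensoryPasses:
    def test_identity_maps_propagate_observation_to_every_level(self):
        grid = set_identity_sensory(sensory_grid([3, 3, 3]))
        v = np.array([0.3, -1.2, 0.7])
        boards = sensory_inference_pass(grid, v)
        for b in boards:
            assert np.allclose(b.bottom_up, v)

    def test_zero_weight_inverse_with_bias_outputs_bias(self):
        grid = sensory_grid([3, 2])
        f = grid.slot(0, 1).pair.inverse
        f.W[:] = 0.0
        f.b[:] = [0.4, -0.2]
        sensory_inference_pass(grid, np.ones(3))
        assert np.allclose(grid.slot(0, 1).board.bottom_up, [0.4, -0.2])

    def test_inference_matches_hand_composed_chain(self, rng):
        grid = sensory_grid([4, 3, 2], seed=5, init_scale=0.5)
        v = rng.standard_normal(4)
        sensory_inference_pass(grid, v)
        # independent oracle: compose the same affine maps by hand (top-down
        # context is zero on the first step)
        x = v
        f0 = grid.slot(0, 0).pair.inverse
        x = f0.W @ np.concatenate([x, np.zeros(4)]) + f0.b
        assert np.allclose(grid.slot(0, 0).board.bottom_up, x, atol=1e-12)
        for k in (1, 2):
            fk = grid.slot(0, k).pair.inverse
            x = fk.W @ np.concatenate([x, np.zeros(len(x))]) + fk.b
            assert np.allclose(grid.slot(0, k).board.bottom_up, x, atol=1e-12)

    def test_generative_matches_hand_composed_chain(self, rng):
        grid = sensory_grid([4, 3, 2], seed=5, init_scale=0.5)
        sensory_inference_pass(grid, rng.standard_normal(4))
        top = rng.standard_normal(2)
        sensory_generative_pass(grid, top)
        xh = top
        for k in (2, 1):
            slot = grid.slot(0, k)
            g = slot.pair.forward
            xh = g.W @ np.concatenate([slot.board.bottom_up, xh]) + g.b
            assert np.allclose(grid.slot(0, k - 1).board.top_down, xh, atol=1e-12)

    def test_dimension_mismatch_raises_shape_error(self):
        grid = sensory_grid([4, 2])
        with pytest.raises(ShapeError):
            sensory_inference_pass(grid, np.zeros(3))
        with pytest.raises(ShapeError):
            sensory_generative_pass(grid, np.zeros(3))


class TestRecurrentSettle:
    def test_one_iteration_equals_single_inference_plus_generative(self, rng):
        a = sensory_grid([4, 2], seed=2)
        b = sensory_grid([4, 2], seed=2)
        v = rng.standard_normal(4)
        recurrent_settle(a, v, n_iters=1)
        sensory_inference_pass(b, v)
        sensory_generative_pass(b, b.slot(0, 1).board.bottom_up)
        for k in range(2):
            assert np.allclose(a.slot(0, k).board.bottom_up, b.slot(0, k).board.bottom_up)
            assert np.allclose(a.slot(0, k).board.top_down, b.slot(0, k).board.top_down)

    def test_matched_pair_has_zero_mismatch_from_first_iteration(self, rng):
        grid = sensory_grid([4, 2])
        frames = set_matched_sensory(grid, rng)
        obs = frames[0] @ frames[1] @ rng.standard_normal(2)  # on the pair's own manifold
        for n_iters in (1, 3):
            recurrent_settle(grid, obs, n_iters=n_iters)
            mism = compute_mismatches(grid, modality=0)
            assert max(mism.values()) < 1e-10

    def test_mismatched_pair_equals_unrolled_oracle(self, rng):
        grid = sensory_grid([3, 2], seed=9, init_scale=0.4)
        v = rng.standard_normal(3)
        recurrent_settle(grid, v, n_iters=3)
        # oracle: unroll the same alternation independently
        f0, f1 = (grid.slot(0, k).pair.inverse for k in range(2))
        g0, g1 = (grid.slot(0, k).pair.forward for k in range(2))
        xh = [np.zeros(3), np.zeros(2)]
        for _ in range(3):
            x0 = f0(np.concatenate([v, xh[0]]))
            x1 = f1(np.concatenate([x0, xh[0]]))
            xh1 = x1  # generative pass re-anchors at the inferred top state
            xh0 = g1(np.concatenate([x1, xh1]))
            recon = g0(np.concatenate([x0, xh0]))
            xh = [xh0, xh1]
        assert np.allclose(grid.slot(0, 0).board.top_down, xh0, atol=1e-12)
        assert np.allclose(grid.slot(0, 0).board.reconstruction, recon, atol=1e-12)

    def test_rejects_non_positive_iteration_count(self):
        grid = sensory_grid([4, 2])
        with pytest.raises(ParameterError):
            recurrent_settle(grid, np.zeros(4), n_iters=0)


class TestMotorPasses:
    def test_identity_controller_passes_goal_down_unchanged(self):
        grid = motor_grid([2, 2])
        for slot in grid.modality_slots(0):
            f = slot.pair.inverse
            slot.pair.inverse = AffineMap.identity_block(f.in_dim, f.out_dim)
        grid.prime_motor(0, np.zeros(2))
        goal = np.array([0.5, -1.0])
        motor_topdown_pass(grid, goal)
        assert np.allclose(grid.slot(0, 1).board.command, goal)
        assert np.allclose(grid.slot(0, 0).board.desired, goal)
        assert np.allclose(grid.slot(0, 0).board.command, goal)

    def test_exact_linear_inverse_drives_predicted_state_to_goal(self, rng):
        # plant x' = A x + B u; the level-0 controller implements the exact
        # inverse u = B^-1 (x_d - A s); the forward model is the true plant map
        A = np.array([[0.9, -0.2], [0.1, 0.7]])
        B = np.array([[1.0, 0.3], [0.0, 0.8]])
        grid = motor_grid([2, 2])
        s0 = grid.slot(0, 0)
        s1 = grid.slot(0, 1)
        Binv = np.linalg.inv(B)
        # f0 input: (x_d, x_hat_0, state)
        s0.pair.inverse = AffineMap(np.hstack([Binv, np.zeros((2, 2)), -Binv @ A]), np.zeros(2))
        s0.pair.forward = AffineMap(np.hstack([A, B]), np.zeros(2))
        s1.pair.inverse = AffineMap.identity_block(6, 2)  # pass the goal down
        s1.pair.forward = AffineMap.identity_block(4, 2)  # abstract = achieved state
        state = rng.standard_normal(2)
        grid.prime_motor(0, state)
        goal = rng.standard_normal(2)
        motor_topdown_pass(grid, goal)
        u = grid.slot(0, 0).board.command
        # oracle: solve B u = x_d - A s by least squares
        u_star = np.linalg.lstsq(B, goal - A @ state, rcond=None)[0]
        assert np.allclose(u, u_star, atol=1e-10)
        motor_bottomup_pass(grid, state)
        assert np.allclose(s0.board.top_down, goal, atol=1e-10)
        mism = compute_mismatches(grid, modality=0)
        assert max(mism.values()) < 1e-10  # desired equals predicted everywhere

    def test_zero_goal_zero_state_zero_bias_gives_zero_command(self):
        grid = motor_grid([2, 2])
        grid.prime_motor(0, np.zeros(2))
        motor_topdown_pass(grid, np.zeros(2))
        assert np.allclose(grid.slot(0, 0).board.command, 0.0)

    def test_topdown_requires_primed_state_estimates(self):
        grid = motor_grid([2, 2])
        with pytest.raises(StateError):
            motor_topdown_pass(grid, np.zeros(2))

    def test_bottomup_requires_commands(self):
        grid = motor_grid([2, 2])
        grid.prime_motor(0, np.zeros(2))
        with pytest.raises(StateError):
            motor_bottomup_pass(grid, np.zeros(2))

    def test_zero_weight_forward_model_outputs_bias(self):
        grid = motor_grid([2, 2])
        grid.prime_motor(0, np.zeros(2))
        motor_topdown_pass(grid, np.ones(2))
        g = grid.slot(0, 0).pair.forward
        g.W[:] = 0.0
        g.b[:] = [0.7, -0.1]
        motor_bottomup_pass(grid, np.zeros(2))
        assert np.allclose(grid.slot(0, 0).board.top_down, [0.7, -0.1])


class TestMismatch:
    def test_three_four_five(self):
        assert mismatch_norm(np.array([3.0, 4.0]), np.zeros(2)) == pytest.approx(5.0)

    def test_symmetry_and_zero(self, rng):
        a, b = rng.standard_normal(4), rng.standard_normal(4)
        assert mismatch_norm(a, b) == mismatch_norm(b, a)
        assert mismatch_norm(a, a) == 0.0

    def test_unequal_dims_raise(self):
        with pytest.raises(ShapeError):
            mismatch_norm(np.zeros(3), np.zeros(2))

    def test_missing_estimates_raise_state_error(self):
        grid = sensory_grid([4, 2])
        with pytest.raises(StateError):
            compute_mismatches(grid)


class TestGatedPairUpdate:
    def _setup(self, rng):
        grid = sensory_grid([4, 2], seed=11)
        slot = grid.slot(0, 1)
        x = rng.standard_normal(4)
        f_in = np.concatenate([x, np.zeros(4)])
        return slot.pair, f_in, x

    def test_zero_responsibility_leaves_parameters_bit_identical(self, rng):
        pair, f_in, x = self._setup(rng)
        before = json.dumps(pair.state_dict())
        gated_pair_update(pair, f_in, x, responsibility=0.0, lr=0.1, g_post=np.zeros(2))
        assert json.dumps(pair.state_dict()) == before

    def test_full_responsibility_step_reduces_mismatch(self, rng):
        pair, f_in, x = self._setup(rng)

        def loss():
            y = pair.inverse(f_in)
            recon = pair.forward(np.concatenate([y, np.zeros(2)]))
            return float(np.sum((recon - x) ** 2))

        before = loss()
        gated_pair_update(pair, f_in, x, responsibility=1.0, lr=1e-3, g_post=np.zeros(2))
        assert loss() < before

    def test_half_responsibility_equals_half_learning_rate(self, rng):
        pair_a, f_in, x = self._setup(rng)
        grid_b = sensory_grid([4, 2], seed=11)
        pair_b = grid_b.slot(0, 1).pair
        gated_pair_update(pair_a, f_in, x, responsibility=0.5, lr=0.1, g_post=np.zeros(2))
        gated_pair_update(pair_b, f_in, x, responsibility=1.0, lr=0.05, g_post=np.zeros(2))
        assert json.dumps(pair_a.state_dict()) == json.dumps(pair_b.state_dict())

    def test_responsibility_outside_unit_interval_rejected(self, rng):
        pair, f_in, x = self._setup(rng)
        with pytest.raises(ParameterError):
            gated_pair_update(pair, f_in, x, responsibility=1.5, lr=0.1, g_post=np.zeros(2))
        with pytest.raises(ParameterError):
            gated_pair_update(pair, f_in, x, responsibility=0.5, lr=-0.1, g_post=np.zeros(2))

    def test_training_on_fixed_linear_world_recovers_parameters(self, rng):
        """Gated learning at full responsibility drives the pair mismatch to
        (numerically) zero on data from a fixed linear generative world."""
        grid = sensory_grid([4, 2], seed=1)
        W = np.linalg.qr(rng.standard_normal((4, 2)))[0]
        for n, lr in ((2500, 0.1), (1500, 0.02)):
            for _ in range(n):
                obs = W @ rng.standard_normal(2)
                for slot in grid.modality_slots(0):
                    slot.board.clear()
                recurrent_settle(grid, obs, n_iters=2)
                slots = grid.modality_slots(0)
                for k in range(2):
                    slot = slots[k]
                    target = obs if k == 0 else slots[k - 1].board.bottom_up
                    gated_pair_update(
                        slot.pair,
                        f_in=slot.board.f_in_cache,
                        target=target,
                        responsibility=1.0,
                        lr=lr,
                        g_post=slot.board.top_down,
                    )
            errs = []
        for _ in range(50):
            obs = W @ rng.standard_normal(2)
            for slot in grid.modality_slots(0):
                slot.board.clear()
            recurrent_settle(grid, obs, n_iters=2)
            errs.append(max(compute_mismatches(grid, modality=0).values()))
        assert np.mean(errs) < 1e-3


class TestMaps:
    def test_mlp_backward_matches_finite_differences(self, rng):
        m = OneHiddenLayerMap.create(3, 2, rng, hidden=5, scale=0.5)
        z = rng.standard_normal(3)
        t = rng.standard_normal(2)
        y = m(z)
        g = y - t
        gz = m.backward(z, g)
        eps = 1e-6

        def loss(zz):
            return 0.5 * float(np.sum((m(zz) - t) ** 2))

        for i in range(3):
            dz = np.zeros(3)
            dz[i] = eps
            num = (loss(z + dz) - loss(z - dz)) / (2 * eps)
            assert num == pytest.approx(gz[i], abs=1e-5)

    def test_affine_sgd_step_converges_on_one_datum(self, rng):
        m = AffineMap.create(3, 2, rng)
        z, t = rng.standard_normal(3), rng.standard_normal(2)
        for _ in range(200):
            m.sgd_step(z, t, lr=0.1)
        assert np.allclose(m(z), t, atol=1e-6)

    def test_map_state_round_trip(self, rng):
        m = OneHiddenLayerMap.create(3, 2, rng, hidden=4)
        d = m.state_dict()
        m2 = OneHiddenLayerMap.create(3, 2, rng, hidden=4)
        m2.load_state_dict(d)
        z = rng.standard_normal(3)
        assert np.array_equal(m(z), m2(z))
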