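import numpy as np
import pytest

import ecofrac as ef
from ecofrac.surrogate import FitReport, _lm_single


def finite_difference_jacobian(net, taus, eps=1e-6):
    """Central-difference oracle for the analytic Jacobian."""
    w0 = net.flatten()
    cols = []
    for i in range(w0.size):
        wp, wm = w0.copy(), w0.copy()
        wp[i] += eps
        wm[i] -= eps
        fp = ef.forward(net.with_flat(wp), taus).ravel()
        fm = ef.forward(net.with_flat(wm), taus).ravel()
        cols.append((fp - fm) / (2 * eps))
    return np.column_stack(cols)


class TestSplit:
    def test_study_grid_sizes(self):
        s = ef.split_indices(101, (0.8, 0.1, 0.1), seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (81, 10, 10)

    def test_exact_proportions(self):
        s = ef.split_indices(10, (0.8, 0.1, 0.1), seed=5)
        assert (len(s.train), len(s.validation), len(s.test)) == (8, 1, 1)

    def test_deterministic_given_seed(self):
        a = ef.split_indices(101, seed=7)
        b = ef.split_indices(101, seed=7)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.validation, b.validation)
        assert np.array_equal(a.test, b.test)

    def test_partition_covers_all_indices_once(self):
        s = ef.split_indices(37, seed=3)
        combined = np.sort(np.concatenate([s.train, s.validation, s.test]))
        assert np.array_equal(combined, np.arange(37))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            ef.split_indices(4, (0.9, 0.05, 0.05), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ef.split_indices(101, (0.8, 0.1, 0.2), seed=0)


class TestInitAndForward:
    def test_deterministic_and_seed_sensitive(self):
        a = ef.init_network(10, seed=4)
        b = ef.init_network(10, seed=4)
        c = ef.init_network(10, seed=5)
        assert np.array_equal(a.flatten(), b.flatten())
        assert not np.array_equal(a.flatten(), c.flatten())

    def test_shapes(self):
        net = ef.init_network(10, seed=0, n_out=3)
        assert net.W1.shape == (10, 1) and net.W2.shape == (3, 10)
        assert net.n_weights == 10 + 10 + 30 + 3

    def test_input_layer_magnitude_follows_nguyen_widrow_factor(self):
        net = ef.init_network(10, seed=0)
        assert np.allclose(np.abs(net.W1), 7.0)  # 0.7 * 10

    def test_zero_weights_give_zero_output(self):
        net = ef.NetworkWeights(W1=np.zeros((4, 1)), b1=np.zeros(4),
                                W2=np.zeros((3, 4)), b2=np.zeros(3))
        assert np.allclose(ef.forward(net, np.linspace(0, 1, 7)), 0.0)

    def test_zero_output_weights_give_constant_biases(self):
        net = ef.NetworkWeights(W1=np.ones((4, 1)), b1=np.ones(4),
                                W2=np.zeros((3, 4)), b2=np.array([1.0, 2.0, 3.0]))
        out = ef.forward(net, np.array([0.1, 0.9]))
        assert np.allclose(out, [[1, 2, 3], [1, 2, 3]])

    def test_non_finite_weights_rejected(self):
        net = ef.init_network(4, seed=0)
        net.W2[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ef.forward(net, 0.5)

    def test_flatten_round_trip(self):
        net = ef.init_network(6, seed=9)
        again = net.with_flat(net.flatten())
        assert np.array_equal(again.flatten(), net.flatten())


class TestJacobian:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            nh = int(rng.integers(2, 6))
            net = ef.init_network(nh, seed=int(rng.integers(1_000)), n_out=3)
            taus = rng.uniform(0, 1, size=7)
            J = ef.jacobian(net, taus)
            J_fd = finite_difference_jacobian(net, taus)
            assert np.max(np.abs(J - J_fd)) / max(np.max(np.abs(J_fd)), 1) < 1e-6

    def test_output_bias_columns_are_indicators(self):
        net = ef.init_network(5, seed=2, n_out=3)
        taus = np.linspace(0, 1, 4)
        J = ef.jacobian(net, taus)
        b2_cols = J[:, -3:]
        expected = np.tile(np.eye(3), (4, 1))
        assert np.array_equal(b2_cols, expected)

    def test_input_weight_columns_vanish_at_zero_normalized_input(self):
        # with b1 = 0 the chain rule gives d out / d W1 proportional to x
        net = ef.NetworkWeights(W1=np.zeros((4, 1)), b1=np.zeros(4),
                                W2=np.ones((3, 4)), b2=np.zeros(3),
                                input_scale=1.0, input_shift=0.0)
        J = ef.jacobian(net, np.array([0.0]))
        assert np.allclose(J[:, :4], 0.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ef.jacobian(ef.init_network(3, seed=0), np.array([]))


class TestLMTrain:
    def test_constant_targets_fit_exactly(self, split101):
        grid = ef.Grid(0.0, 0.01, 100)
        states = np.tile([0.3, 0.6, 0.9], (101, 1))
        traj = ef.Trajectory(grid=grid, states=states)
        # disable the gradient stop so training runs to representability
        rep = ef.lm_train(traj, split101,
                          ef.TrainConfig(seed=0, max_epochs=50, grad_tol=0.0))
        assert rep.final_mse_train <= 1e-20

    def test_accepted_step_training_mse_non_increasing(self, sin_trajectory, split101):
        rep = ef.lm_train(sin_trajectory, split101,
                          ef.TrainConfig(seed=3, max_epochs=200))
        diffs = np.diff(rep.mse_train)
        assert (diffs <= 0).all()

    def test_end_to_end_determinism(self, sin_trajectory, split101):
        cfg = ef.TrainConfig(seed=12, max_epochs=60, restarts=2)
        r1 = ef.lm_train(sin_trajectory, split101, cfg)
        r2 = ef.lm_train(sin_trajectory, split101, cfg)
        assert r1.mse_train == r2.mse_train
        assert r1.stop_reason == r2.stop_reason
        assert np.array_equal(r1.weights.flatten(), r2.weights.flatten())

    def test_sine_fit_reaches_reference_accuracy(self, sin_trajectory, split101):
        """Best of 5 restarts matches what an established damped least-squares
        optimizer achieves on the identical architecture (MSE <= 1e-8)."""
        rep = ef.lm_train(sin_trajectory, split101,
                          ef.TrainConfig(seed=0, restarts=5))
        assert rep.final_mse_train <= 1e-8

    def test_restart_selection_prefers_lowest_validation(self, sin_trajectory, split101):
        cfg = ef.TrainConfig(seed=0, restarts=4, max_epochs=100)
        best = ef.lm_train(sin_trajectory, split101, cfg)
        singles = [
            _lm_single(sin_trajectory.times, sin_trajectory.states, split101,
                       cfg, seed=s, n_out=1)
            for s in range(4)
        ]
        assert best.final_mse_validation == min(s.final_mse_validation for s in singles)

    def test_damping_limits(self):
        """mu -> inf approaches the (scaled) negative gradient direction;
        mu -> 0 approaches the Gauss-Newton step."""
        rng = np.random.default_rng(0)
        net = ef.init_network(4, seed=1, n_out=1)
        taus = np.linspace(0, 1, 20)
        y = np.sin(taus)[:, None]
        J = ef.jacobian(net, taus)
        r = (ef.forward(net, taus) - y).ravel()
        JtJ, Jtr = J.T @ J, J.T @ r
        D = np.diag(np.maximum(np.diag(JtJ), 1e-12))

        big = np.linalg.solve(JtJ + 1e12 * D, -Jtr)
        grad_dir = np.linalg.solve(D, -Jtr)
        cos = big @ grad_dir / (np.linalg.norm(big) * np.linalg.norm(grad_dir))
        assert cos == pytest.approx(1.0, abs=1e-6)

        small = np.linalg.solve(JtJ + 1e-14 * D, -Jtr)
        gn = np.linalg.lstsq(JtJ, -Jtr, rcond=None)[0]
        assert np.allclose(small, gn, rtol=1e-5)

    def test_per_output_mode_builds_block_diagonal_network(self, traj_case1, split101):
        cfg = ef.TrainConfig(seed=0, max_epochs=10, n_hidden=4)
        rep = ef.lm_train(traj_case1, split101, cfg, joint=False)
        net = rep.weights
        assert net.W1.shape == (12, 1) and net.W2.shape == (3, 12)
        # cross-output blocks are zero
        assert np.allclose(net.W2[0, 4:], 0.0)
        assert np.allclose(net.W2[1, :4], 0.0) and np.allclose(net.W2[1, 8:], 0.0)
        assert np.allclose(net.W2[2, :8], 0.0)

    def test_mismatched_split_rejected(self, sin_trajectory):
        bad = ef.split_indices(50, seed=0)
        with pytest.raises(ValueError, match="split"):
            ef.lm_train(sin_trajectory, bad, ef.TrainConfig(seed=0))


class TestFitReportIO:
    def test_json_round_trip_is_lossless(self, sin_trajectory, split101, tmp_path):
        rep = ef.lm_train(sin_trajectory, split101,
                          ef.TrainConfig(seed=1, max_epochs=20))
        path = tmp_path / "fit.json"
        rep.to_json(path)
        back = FitReport.from_json(path)
        assert back.mse_train == rep.mse_train
        assert back.stop_reason == rep.stop_reason
        assert np.array_equal(back.weights.flatten(), rep.weights.flatten())
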