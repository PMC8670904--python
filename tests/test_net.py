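"""Operator-equation oracles, gradient correctness, and training behavior."""

import numpy as np
import pytest

from pulsebp.net import (
    ABPNet,
    TrainConfig,
    batch_norm_forward,
    conv1d_forward,
    global_average,
    load_model,
    mse_loss,
    pool,
    predict,
    relu,
    save_model,
    train,
)


def conv_oracle(u, w, b, stride):
    """Triple-loop direct evaluation of the convolution equation."""
    n, length = u.shape
    _, m, k = w.shape
    l_out = (length - k) // stride + 1
    v = np.zeros((m, l_out))
    for j in range(m):
        for x in range(l_out):
            acc = b[j]
            for i in range(n):
                for p in range(k):
                    acc += w[i, j, p] * u[i, x * stride + p]
            v[j, x] = acc
    return v


class TestConv1d:
    def test_identity_kernel(self):
        u = np.array([[1.0, 2.0, 3.0, 4.0]])
        w = np.ones((1, 1, 1))
        out = conv1d_forward(u, w, np.zeros(1), stride=1)
        np.testing.assert_array_equal(out, u)

    def test_difference_kernel(self):
        u = np.array([[1.0, 2.0, 3.0, 4.0]])
        w = np.array([1.0, -1.0]).reshape(1, 1, 2)
        out = conv1d_forward(u, w, np.zeros(1), stride=1)
        np.testing.assert_allclose(out, [[-1.0, -1.0, -1.0]])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(2, 10))
        w = rng.normal(size=(2, 3, 3))
        b = rng.normal(size=3)
        for stride in (1, 2, 3):
            np.testing.assert_allclose(
                conv1d_forward(u, w, b, stride), conv_oracle(u, w, b, stride),
                rtol=1e-12,
            )

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            conv1d_forward(np.zeros((1, 3)), np.zeros((1, 1, 5)), np.zeros(1))


class TestBatchNorm:
    def test_zero_variance_batch_maps_to_beta(self):
        out = batch_norm_forward([2.0, 2.0, 2.0], gamma=1.0, beta=5.0)
        np.testing.assert_allclose(out, 5.0, atol=1e-3)

    def test_three_point_batch_standardized(self):
        out = batch_norm_forward([1.0, 2.0, 3.0], eps=1e-12)
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_output_moments_are_beta_and_gamma_squared(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3.0, 2.0, size=64)
        out = batch_norm_forward(x, gamma=1.7, beta=-0.3, eps=1e-15)
        assert out.mean() == pytest.approx(-0.3, abs=1e-6)
        assert out.var() == pytest.approx(1.7**2, abs=1e-6)

    def test_single_value_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_norm_forward([1.0])

    def test_conv_statistic_pools_positions_across_batch(self):
        from pulsebp.net import _BatchNorm

        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 2, 9))
        bn = _BatchNorm(2)
        out = bn.forward(x, training=True)
        for c in range(2):
            expected = batch_norm_forward(x[:, c, :].ravel(), eps=bn.eps)
            np.testing.assert_allclose(out[:, c, :].ravel(), expected, rtol=1e-10)


class TestPoolAndAvg:
    def test_max_pool_example(self):
        np.testing.assert_array_equal(
            pool(np.array([[1.0, 3.0, 2.0, 5.0]]), 2, 2, "max"), [[3.0, 5.0]]
        )

    def test_mean_pool_example(self):
        np.testing.assert_array_equal(
            pool(np.array([[1.0, 3.0, 2.0, 5.0]]), 2, 2, "mean"), [[2.0, 3.5]]
        )

    def test_unit_window_is_identity(self):
        x = np.random.default_rng(0).normal(size=(2, 7))
        for mode in ("max", "mean"):
            np.testing.assert_array_equal(pool(x, 1, 1, mode), x)

    def test_global_average_equals_full_width_mean_pool(self):
        x = np.random.default_rng(3).normal(size=(3, 11))
        np.testing.assert_allclose(
            global_average(x), pool(x, 11, 1, "mean")[:, 0], rtol=1e-12
        )

    def test_window_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            pool(np.zeros((1, 3)), 5, 1, "max")


class TestReluAndLoss:
    def test_relu_elementwise(self):
        np.testing.assert_array_equal(relu([-3.0, 0.0, 2.5]), [0.0, 0.0, 2.5])

    def test_mse_examples(self):
        assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mse_loss([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_mse_permutation_invariant_over_pairs(self):
        y = np.array([1.0, 5.0, -2.0])
        yh = np.array([0.0, 4.0, 1.0])
        perm = [2, 0, 1]
        assert mse_loss(y, yh) == pytest.approx(mse_loss(y[perm], yh[perm]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([1.0], [1.0, 2.0])


def finite_difference_max_error(model, ppg, ptt, y, n_probe=4, h=1e-6):
    """Largest relative difference between analytic and central-difference grads."""
    def loss():
        out = model.forward(ppg, ptt, training=True)
        return np.mean((out - y) ** 2)

    out = model.forward(ppg, ptt, training=True)
    err = out - y
    model.backward(2.0 * err / err.size)
    rng = np.random.default_rng(99)
    worst = 0.0
    for value, grad in model.parameters():
        flat_v, flat_g = value.ravel(), grad.ravel()
        for i in rng.choice(flat_v.size, size=min(n_probe, flat_v.size), replace=False):
            old = flat_v[i]
            flat_v[i] = old + h
            lp = loss()
            flat_v[i] = old - h
            lm = loss()
            flat_v[i] = old
            fd = (lp - lm) / (2 * h)
            denom = max(abs(fd), abs(flat_g[i]), 1e-8)
            worst = max(worst, abs(fd - flat_g[i]) / denom)
    return worst


class TestABPNet:
    def _mini(self, seed=1, **kw):
        kw.setdefault("input_len", 32)
        kw.setdefault("channels", (2, 3, 4))
        kw.setdefault("kernel", 3)
        kw.setdefault("fc_hidden", 5)
        return ABPNet(seed=seed, **kw)

    def test_forward_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        ppg = rng.normal(size=(4, 32))
        ptt = rng.normal(size=(4, 2))
        out1 = self._mini(seed=7).forward(ppg, ptt)
        out2 = self._mini(seed=7).forward(ppg, ptt)
        np.testing.assert_array_equal(out1, out2)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        model = self._mini()
        worst = finite_difference_max_error(
            model, rng.normal(size=(6, 32)), rng.normal(size=(6, 2)),
            rng.normal(size=(6, 2)),
        )
        assert worst <= 1e-4

    def test_zeroed_waveform_path_depends_only_on_ptt(self):
        model = self._mini()
        for conv in (model.conv1, model.conv2, model.conv3, model.skip):
            conv.w[...] = 0.0
            conv.b[...] = 0.0
        model.fc1.w[: -model.n_ptt, :] = 0.0  # cut the waveform rows of FC1
        rng = np.random.default_rng(5)
        ptt = rng.normal(size=(3, 2))
        out1 = model.forward(rng.normal(size=(3, 32)), ptt)
        out2 = model.forward(rng.normal(size=(3, 32)), ptt)
        np.testing.assert_allclose(out1, out2, rtol=1e-12)
        out3 = model.forward(np.zeros((3, 32)), ptt + 0.5)
        assert not np.allclose(out1, out3)

    def test_residual_connection_is_live(self):
        rng = np.random.default_rng(6)
        ppg = rng.normal(size=(3, 32))
        ptt = rng.normal(size=(3, 2))
        with_res = self._mini(seed=2, use_residual=True).forward(ppg, ptt)
        without = self._mini(seed=2, use_residual=False).forward(ppg, ptt)
        assert not np.allclose(with_res, without)

    def test_inconsistent_geometry_rejected_at_build_time(self):
        with pytest.raises(ValueError):
            ABPNet(input_len=16, channels=(2, 3, 4), kernel=9)

    def test_wrong_input_length_rejected(self):
        model = self._mini()
        with pytest.raises(ValueError, match="length"):
            model.forward(np.zeros((2, 64)), np.zeros((2, 2)))


def _affine_task(n=300, seed=0):
    rng = np.random.default_rng(seed)
    ptt = np.empty((n, 2))
    ptt[:, 0] = rng.uniform(0.18, 0.30, size=n)
    ptt[:, 1] = ptt[:, 0] + 0.3
    y = np.column_stack([300 - 700 * ptt[:, 0], 200 - 450 * ptt[:, 0]])
    ppg = rng.uniform(0, 1, size=(n, 32))
    return ppg, ptt, y


class TestTraining:
    def test_affine_target_learned_below_one_mmhg2(self):
        ppg, ptt, y = _affine_task()
        model = ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=0)
        hist = train(model, ppg, ptt, y, TrainConfig(n_epochs=120, learning_rate=0.05, seed=0))
        assert hist["val_mse"][-1] < 1.0
        pred = predict(model, ppg, ptt)
        assert np.mean(np.abs(pred - y)) < 1.0

    def test_zero_learning_rate_freezes_parameters(self):
        ppg, ptt, y = _affine_task(n=120)
        model = ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=3)
        before = [v.copy() for v, _ in model.parameters()]
        hist = train(model, ppg, ptt, y,
                     TrainConfig(n_epochs=3, learning_rate=0.0, batch_size=None, seed=0))
        for (v, _), b in zip(model.parameters(), before):
            np.testing.assert_array_equal(v, b)
        assert hist["train_mse"][0] == pytest.approx(hist["train_mse"][-1])

    def test_loss_descends_from_first_epoch(self):
        ppg, ptt, y = _affine_task(n=200, seed=4)
        model = ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=4)
        hist = train(model, ppg, ptt, y, TrainConfig(n_epochs=40, seed=4))
        assert hist["train_mse"][-1] <= hist["train_mse"][0]

    def test_identical_seed_reproduces_history(self):
        ppg, ptt, y = _affine_task(n=120)
        h1 = train(ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=5),
                   ppg, ptt, y, TrainConfig(n_epochs=5, seed=5))
        h2 = train(ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=5),
                   ppg, ptt, y, TrainConfig(n_epochs=5, seed=5))
        assert h1 == h2

    def test_divergence_aborts_with_epoch_number(self):
        ppg, ptt, y = _affine_task(n=120)
        model = ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=0)
        with pytest.raises(FloatingPointError, match="epoch"):
            train(model, ppg, ptt, y, TrainConfig(n_epochs=60, learning_rate=1e4, seed=0))

    def test_batch_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=1).validate()


class TestPredict:
    def test_prediction_deterministic_and_order_equivariant(self):
        ppg, ptt, y = _affine_task(n=120)
        model = ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=1)
        train(model, ppg, ptt, y, TrainConfig(n_epochs=5, seed=1))
        p1 = predict(model, ppg, ptt)
        p2 = predict(model, ppg, ptt)
        np.testing.assert_array_equal(p1, p2)
        perm = np.random.default_rng(0).permutation(len(ppg))
        np.testing.assert_allclose(predict(model, ppg[perm], ptt[perm]), p1[perm],
                                   rtol=1e-12)

    def test_save_load_round_trip(self, tmp_path):
        ppg, ptt, y = _affine_task(n=120)
        model = ABPNet(input_len=32, channels=(2, 3, 4), kernel=3, fc_hidden=8, seed=1)
        train(model, ppg, ptt, y, TrainConfig(n_epochs=3, seed=1))
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(predict(back, ppg, ptt), predict(model, ppg, ptt),
                                   rtol=1e-12)
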