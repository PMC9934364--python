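"""CNN engine: exact gradients, layer semantics, training loop contracts."""

import numpy as np
import pytest

from epishape import nn
from epishape.model_zoo import ArchSpec, build_cnn


def naive_conv_same(x, W, b):
    """Direct quadruple-loop stride-1 'same' cross-correlation (NCHW)."""
    B, C, H, Wd = x.shape
    F, _, k, _ = W.shape
    p = k // 2
    xp = np.zeros((B, C, H + 2 * p, Wd + 2 * p), dtype=x.dtype)
    xp[:, :, p : p + H, p : p + Wd] = x
    y = np.zeros((B, F, H, Wd), dtype=x.dtype)
    for f in range(F):
        for c in range(C):
            for u in range(k):
                for v in range(k):
                    y[:, f] += xp[:, c, u : u + H, v : v + Wd] * W[f, c, u, v]
    return y + b[None, :, None, None]


def fd_check(layer, xshape, rng, n_samples=10, eps=1e-6):
    """Finite-difference check of parameter and input gradients."""
    X = rng.standard_normal(xshape)
    out = layer.forward(X, training=True, rng=rng)
    T = rng.standard_normal(out.shape)
    lossv = lambda o: float(np.sum(o * T))
    dX = layer.backward(T.copy())
    worst = 0.0
    for p, g in zip(layer.params(), layer.grads()):
        flat = np.unravel_index(
            rng.choice(p.size, size=min(n_samples, p.size), replace=False), p.shape
        )
        for j in range(len(flat[0])):
            ix = tuple(f[j] for f in flat)
            old = p[ix]
            p[ix] = old + eps
            lp = lossv(layer.forward(X))
            p[ix] = old - eps
            lm = lossv(layer.forward(X))
            p[ix] = old
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - g[ix]) / max(1e-10, abs(num) + abs(g[ix])))
    flat = np.unravel_index(rng.choice(X.size, size=n_samples, replace=False), X.shape)
    for j in range(n_samples):
        ix = tuple(f[j] for f in flat)
        Xp, Xm = X.copy(), X.copy()
        Xp[ix] += eps
        Xm[ix] -= eps
        num = (lossv(layer.forward(Xp)) - lossv(layer.forward(Xm))) / (2 * eps)
        worst = max(worst, abs(num - dX[ix]) / max(1e-10, abs(num) + abs(dX[ix])))
    return worst


class TestConv2D:
    @pytest.mark.parametrize("cin,cout,k,H,W", [(1, 3, 3, 8, 8), (2, 4, 5, 7, 9),
                                                (3, 2, 9, 16, 12)])
    def test_forward_matches_naive(self, cin, cout, k, H, W, rng):
        conv = nn.Conv2D(cin, cout, k, rng, dtype=np.float64)
        X = rng.standard_normal((2, cin, H, W))
        assert np.allclose(conv.forward(X), naive_conv_same(X, conv.W, conv.b),
                           atol=1e-10)

    @pytest.mark.parametrize("cin,cout,k,H,W", [(2, 3, 3, 8, 8), (3, 2, 5, 7, 9),
                                                (1, 4, 9, 16, 16)])
    def test_gradients_exact(self, cin, cout, k, H, W, rng):
        conv = nn.Conv2D(cin, cout, k, rng, dtype=np.float64)
        assert fd_check(conv, (2, cin, H, W), rng) < 1e-6

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            nn.Conv2D(1, 1, 4, rng)


class TestOtherLayers:
    def test_maxpool_values_and_gradient(self, rng):
        x = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        pool = nn.MaxPool2()
        out = pool.forward(x, training=True)
        assert np.array_equal(out[0, 0], [[5, 7], [13, 15]])
        assert fd_check(nn.MaxPool2(), (2, 3, 8, 8), rng) < 1e-6

    def test_dense_gradient(self, rng):
        assert fd_check(nn.Dense(10, 4, rng, dtype=np.float64), (5, 10), rng) < 1e-6

    def test_dropout_inference_is_identity(self, rng):
        d = nn.Dropout(0.5)
        x = rng.standard_normal((4, 3, 8, 8))
        assert d.forward(x, training=False) is x

    def test_dropout_preserves_expectation(self, rng):
        d = nn.Dropout(0.2)
        x = np.ones((1, 1, 200, 200), dtype=np.float64)
        out = d.forward(x, training=True, rng=rng)
        assert out.mean() == pytest.approx(1.0, abs=0.02)
        kept = out[out > 0]
        assert np.allclose(kept, 1 / 0.8)


class TestNetwork:
    def test_zero_weights_output_is_bias(self, rng):
        arch = ArchSpec([(1, 3)], input_size=16)
        net = build_cnn(arch, seed=0)
        net.set_weights([np.zeros_like(p) for p in net.params()])
        dense_b = net.params()[-1]
        dense_b[...] = [1.0, 2.0, 3.0, 4.0]
        out = net.predict(rng.random((3, 1, 16, 16)).astype(np.float32))
        assert np.allclose(out, [[1, 2, 3, 4]] * 3, atol=1e-6)

    def test_full_net_gradients(self, rng):
        """Composite finite-difference check (kinks allowed at ReLU/pool)."""
        arch = ArchSpec([(2, 3), (3, 5)], input_size=8, dropout_rate=0.0)
        net = build_cnn(arch, seed=1, dtype=np.float64)
        X = rng.standard_normal((3, 1, 8, 8))
        y = rng.standard_normal((3, 4))
        loss = nn.MSELoss()
        pred = net.forward(X, training=True, rng=rng)
        net.backward(loss.grad(pred, y))
        errs = []
        for p, g in zip(net.params(), net.grads()):
            flat = np.unravel_index(
                rng.choice(p.size, size=min(6, p.size), replace=False), p.shape
            )
            for j in range(len(flat[0])):
                ix = tuple(f[j] for f in flat)
                eps, old = 1e-6, p[ix]
                p[ix] = old + eps
                lp = loss.value(net.forward(X), y)
                p[ix] = old - eps
                lm = loss.value(net.forward(X), y)
                p[ix] = old
                num = (lp - lm) / (2 * eps)
                errs.append(abs(num - g[ix]) / max(1e-10, abs(num) + abs(g[ix])))
        assert np.median(errs) < 1e-6
        assert np.quantile(errs, 0.9) < 1e-4


class TestFit:
    def _toy(self, rng, n=64):
        X = rng.random((n, 1, 8, 8)).astype(np.float32)
        y = X.mean(axis=(1, 2, 3), keepdims=False)[:, None] * np.ones((1, 4))
        return X, y.astype(np.float32)

    def test_loss_decreases(self, rng):
        X, y = self._toy(rng)
        net = build_cnn(ArchSpec([(4, 3)], input_size=8, dropout_rate=0.0), seed=0)
        hist = nn.fit(net, X, y, epochs=30, batch_size=16, seed=0)
        assert hist.train_loss[-1] < 0.25 * hist.train_loss[0]

    def test_early_stop_restores_best(self, rng):
        X, y = self._toy(rng)
        net = build_cnn(ArchSpec([(2, 3)], input_size=8), seed=0)
        hist = nn.fit(net, X[:48], y[:48], X[48:], y[48:], epochs=60,
                      batch_size=16, patience=5, seed=0)
        assert min(hist.val_loss) == hist.val_loss[hist.best_epoch]
        final = nn.MSELoss().value(net.predict(X[48:]), y[48:])
        assert final == pytest.approx(min(hist.val_loss), rel=1e-5)

    def test_patience_zero_stops_at_first_plateau(self, rng):
        X, y = self._toy(rng)
        net = build_cnn(ArchSpec([(2, 3)], input_size=8), seed=0)
        hist = nn.fit(net, X[:48], y[:48], X[48:], y[48:], epochs=100,
                      batch_size=16, patience=0, seed=0)
        if hist.stopped_early:
            # stopped exactly one epoch after the best
            assert len(hist.val_loss) == hist.best_epoch + 2

    def test_deterministic_given_seed(self, rng):
        X, y = self._toy(rng)
        h1 = nn.fit(build_cnn(ArchSpec([(2, 3)], input_size=8), seed=3), X, y,
                    epochs=3, seed=9)
        h2 = nn.fit(build_cnn(ArchSpec([(2, 3)], input_size=8), seed=3), X, y,
                    epochs=3, seed=9)
        assert h1.train_loss == h2.train_loss


class TestPeriodicMSE:
    def test_wraparound_not_penalized(self):
        loss = nn.PeriodicMSELoss()
        pred = np.array([[0.0, 0.0, 0.01]])
        y = np.array([[0.0, 0.0, np.pi - 0.01]])
        assert loss.value(pred, y) == pytest.approx((0.02) ** 2 / 3)

    def test_gradient_matches_fd(self, rng):
        loss = nn.PeriodicMSELoss()
        pred = rng.standard_normal((4, 3))
        y = rng.standard_normal((4, 3))
        g = loss.grad(pred.copy(), y)
        eps = 1e-6
        for ix in [(0, 0), (1, 2), (3, 1)]:
            pp, pm = pred.copy(), pred.copy()
            pp[ix] += eps
            pm[ix] -= eps
            num = (loss.value(pp, y) - loss.value(pm, y)) / (2 * eps)
            assert num == pytest.approx(g[ix], abs=1e-5)
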