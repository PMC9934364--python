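"""A small CNN engine on NumPy: the layers, losses and optimizer used here.

The networks in this package are deliberately tiny (a few layers, at most a
couple hundred thousand weights), so a direct NumPy implementation is adequate
for CPU training and inference.  Convolutions are evaluated in the Fourier
domain (real 2-D FFTs with per-frequency batched channel contractions), which
avoids the large im2col buffers that dominate the cost of a spatial
implementation at these shapes.  The engine provides exactly the pieces the
architecture family needs: stride-1 zero-padded ("same") convolution, ReLU,
2x2 max pooling, inverted dropout, flatten, a linear dense layer,
mean-squared-error (plus a periodic variant for raw-angle regression), and
Adam with minibatch shuffling, early stopping and best-weight restoration.

Conventions: activations are NCHW ``float32`` by default (``float64`` is
supported for gradient checking); convolution weights have shape
(c_out, c_in, k, k); all randomness (initialization, shuffling, dropout)
derives from ``numpy.random.Generator`` objects seeded by the caller.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "MSELoss",
    "PeriodicMSELoss",
    "Adam",
    "fit",
    "TrainHistory",
]


def _glorot_uniform(rng, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: optional parameters, forward pass, backward pass."""

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy, need_input_grad=True):  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 cross-correlation with zero "same" padding, odd kernels.

    All three passes are linear convolutions evaluated exactly on a common
    zero-padded FFT grid S >= H + k - 1.  With p = k//2:

    * forward:          y  = crop[p : p+H] conv_full(x, flip W),  sum over c_in
    * input gradient:   dx = crop[p : p+H] conv_full(dy, W),      sum over c_out
    * weight gradient:  dW = crop[H-1-p : H-1-p+k] conv_full(x, flip dy),
      summed over the batch.

    The transform of the flipped gradient is obtained from the transform of
    the gradient itself through conjugation and a linear phase (reversal
    theorem), so each backward pass costs one FFT of dy, two frequency-domain
    contractions and two inverse FFTs.
    """

    def __init__(self, c_in, c_out, k, rng, dtype=np.float32):
        if k % 2 != 1 or k < 1:
            raise ValueError("kernel size must be odd and >= 1")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.W = _glorot_uniform(rng, (c_out, c_in, k, k), fan_in, fan_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    _idft_cache: dict = {}
    _dft_cache: dict = {}

    @classmethod
    def _dft_kernel_matrix(cls, S, f0, f1, k, cdtype):
        """(k*k, f0*f1) matrix: zero-padded forward rfft2 of a k x k kernel."""
        key = (S, f0, f1, k, np.dtype(cdtype).name)
        D = cls._dft_cache.get(key)
        if D is None:
            j0 = np.arange(f0)
            j1 = np.arange(f1)
            u = np.arange(k)
            e0 = np.exp(-2j * np.pi * np.outer(u, j0) / S[0])  # (k, f0)
            e1 = np.exp(-2j * np.pi * np.outer(u, j1) / S[1])  # (k, f1)
            D = (e0[:, None, :, None] * e1[None, :, None, :]).reshape(
                k * k, f0 * f1
            ).astype(cdtype)
            cls._dft_cache[key] = D
        return D

    @classmethod
    def _idft_crop_matrix(cls, S, f0, f1, r0, r1, k, cdtype):
        """(f0*f1, k*k) matrix evaluating the inverse rfft2 at a k x k crop.

        Row (j0, j1) of the half-spectrum contributes with weight 2 except for
        the self-conjugate columns j1 = 0 and (if S1 is even) j1 = S1/2.
        """
        key = (S, f0, f1, r0, r1, k, np.dtype(cdtype).name)
        E = cls._idft_cache.get(key)
        if E is None:
            j0 = np.arange(f0)
            j1 = np.arange(f1)
            n0 = r0 + np.arange(k)
            n1 = r1 + np.arange(k)
            e0 = np.exp(2j * np.pi * np.outer(j0, n0) / S[0])  # (f0, k)
            e1 = np.exp(2j * np.pi * np.outer(j1, n1) / S[1])  # (f1, k)
            c = np.full(f1, 2.0)
            c[0] = 1.0
            if S[1] % 2 == 0 and f1 == S[1] // 2 + 1:
                c[-1] = 1.0
            e1 = e1 * c[:, None]
            E = (e0[:, None, :, None] * e1[None, :, None, :]).reshape(
                f0 * f1, k * k
            ) / (S[0] * S[1])
            E = E.astype(cdtype)
            cls._idft_cache[key] = E
        return E

    def forward(self, x, training=False, rng=None):
        B, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        p = self.k // 2
        S = (sfft.next_fast_len(H + self.k - 1, real=True),
             sfft.next_fast_len(W + self.k - 1, real=True))
        xh = sfft.rfft2(x, s=S)  # (B, c_in, S0, S1//2+1)
        f0, f1 = xh.shape[-2], xh.shape[-1]
        nf = f0 * f1
        D = self._dft_kernel_matrix(S, f0, f1, self.k, xh.dtype)
        wflip = self.W[:, :, ::-1, ::-1].reshape(-1, self.k * self.k)
        wh = (wflip.astype(xh.real.dtype) @ D).reshape(self.c_out, C, nf)
        xm = np.ascontiguousarray(xh.reshape(B, C, nf).transpose(2, 0, 1))
        wm = wh.transpose(2, 1, 0)  # (freq, c_in, c_out)
        ym = xm @ wm  # (freq, B, c_out)
        yh = ym.transpose(1, 2, 0).reshape(B, self.c_out, f0, f1)
        y = sfft.irfft2(yh, s=S)[:, :, p : p + H, p : p + W]
        y = np.ascontiguousarray(y).astype(x.dtype, copy=False)
        y += self.b[:, None, None]
        if training:
            self._xm, self._in_shape, self._S, self._nfreq = xm, x.shape, S, (f0, f1)
        return y

    def backward(self, dy, need_input_grad=True):
        B, C, H, W = self._in_shape
        k, p = self.k, self.k // 2
        S = self._S
        f0, f1 = self._nfreq
        nf = f0 * f1
        self.db[...] = dy.sum(axis=(0, 2, 3)).astype(self.db.dtype, copy=False)

        dyh = sfft.rfft2(dy, s=S)  # (B, c_out, f0, f1)
        gm = np.ascontiguousarray(dyh.reshape(B, self.c_out, nf).transpose(2, 0, 1))

        # transform of the spatially flipped dy via the reversal theorem
        w0 = np.exp(-2j * np.pi * np.arange(f0) * ((H - 1) % S[0]) / S[0])
        w1 = np.exp(-2j * np.pi * np.arange(f1) * ((W - 1) % S[1]) / S[1])
        phase = (w0[:, None] * w1[None, :]).reshape(nf).astype(gm.dtype)
        gm_flip = np.conj(gm) * phase[:, None, None]

        # dW: (freq, c_in, B) @ (freq, B, c_out) -> (freq, c_in, c_out)
        wg = self._xm.transpose(0, 2, 1) @ gm_flip
        # only a k x k crop of the inverse transform is needed, so evaluate
        # the inverse DFT directly at those k*k points
        E = self._idft_crop_matrix(S, f0, f1, H - 1 - p, W - 1 - p, k, wg.dtype)
        wflat = wg.transpose(1, 2, 0).reshape(C * self.c_out, nf) @ E
        self.dW[...] = (
            wflat.real.reshape(C, self.c_out, k, k).transpose(1, 0, 2, 3)
            .astype(self.dW.dtype, copy=False)
        )
        self._xm = None

        if not need_input_grad:
            return None
        D = self._dft_kernel_matrix(S, f0, f1, k, gm.dtype)
        wh = (self.W.reshape(-1, k * k).astype(gm.real.dtype) @ D).reshape(
            self.c_out, C, nf
        )
        wm = wh.transpose(2, 0, 1)  # (freq, c_out, c_in)
        dxm = gm @ wm  # (freq, B, c_in)
        dxh = dxm.transpose(1, 2, 0).reshape(B, C, f0, f1)
        dx = sfft.irfft2(dxh, s=S)[:, :, p : p + H, p : p + W]
        return np.ascontiguousarray(dx).astype(dy.dtype, copy=False)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0 if training else None
        return np.maximum(x, 0)

    def backward(self, dy, need_input_grad=True):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x, training=False, rng=None):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = np.ascontiguousarray(r).reshape(B, C, H // 2, W // 2, 4)
        idx = np.argmax(r, axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._in_shape = idx, x.shape
        return out

    def backward(self, dy, need_input_grad=True):
        B, C, H, W = self._in_shape
        dr = np.zeros((B, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dr).reshape(B, C, H, W)


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dy, need_input_grad=True):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, need_input_grad=True):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer with linear activation."""

    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        self.W = _glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False, rng=None):
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, dy, need_input_grad=True):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T if need_input_grad else None


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def num_params(self):
        return int(sum(p.size for p in self.params()))

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            dy = layer.backward(dy, need_input_grad=not last)
        return dy

    def predict(self, x, batch_size=64):
        """Inference (dropout off), in minibatches to bound memory."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i : i + batch_size], training=False))
        return np.concatenate(outs, axis=0)

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class MSELoss:
    """Mean squared error over all outputs (mean over batch and targets)."""

    def value(self, pred, y):
        d = pred - y
        return float(np.mean(d * d))

    def grad(self, pred, y):
        return ((2.0 / pred.size) * (pred - y)).astype(pred.dtype, copy=False)


class PeriodicMSELoss:
    """MSE on the leading targets plus a pi-periodic squared error on the last.

    For 3-output models that regress (zL, zl, alpha) directly: the angular
    residual is folded to [-pi/2, pi/2) before squaring, so predictions near
    pi for a truth near 0 are not penalized.
    """

    def _residual(self, pred, y):
        d = (pred - y).astype(np.float64)
        d[:, -1] = np.mod(d[:, -1] + np.pi / 2, np.pi) - np.pi / 2
        return d

    def value(self, pred, y):
        d = self._residual(pred, y)
        return float(np.mean(d * d))

    def grad(self, pred, y):
        d = self._residual(pred, y)
        return ((2.0 / pred.size) * d).astype(pred.dtype, copy=False)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TrainHistory:
    """Per-epoch training record; convertible to a DataFrame/CSV."""

    def __init__(self):
        self.epochs = []
        self.train_loss = []
        self.val_loss = []
        self.best_epoch = -1
        self.stopped_early = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            dict(epoch=self.epochs, train_loss=self.train_loss, val_loss=self.val_loss)
        )


def fit(
    net,
    X,
    y,
    X_val=None,
    y_val=None,
    *,
    epochs=200,
    batch_size=32,
    lr=1e-3,
    patience=20,
    loss=None,
    seed=0,
    verbose=False,
):
    """Minibatch Adam training with early stopping on validation loss.

    When validation data is given, training stops after ``patience`` epochs
    without improvement and the best-epoch weights are restored (patience 0
    stops at the first non-improving epoch).  Returns a ``TrainHistory``.
    """
    loss = loss or MSELoss()
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=lr)
    hist = TrainHistory()
    best_val = np.inf
    best_weights = None
    since_best = 0
    n = X.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xb, yb = X[idx], y[idx]
            pred = net.forward(xb, training=True, rng=rng)
            total += loss.value(pred, yb) * len(idx)
            seen += len(idx)
            net.backward(loss.grad(pred, yb))
            opt.step(net.grads())
        hist.epochs.append(epoch)
        hist.train_loss.append(total / seen)
        if X_val is not None:
            vl = loss.value(net.predict(X_val), y_val)
            hist.val_loss.append(vl)
            if vl < best_val:
                best_val = vl
                best_weights = net.get_weights()
                hist.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best > patience:
                    hist.stopped_early = True
                    break
        else:
            hist.val_loss.append(np.nan)
        if verbose:
            print(f"epoch {epoch}: train {hist.train_loss[-1]:.5f} "
                  f"val {hist.val_loss[-1]:.5f}", flush=True)
    if best_weights is not None:
        net.set_weights(best_weights)
    return hist
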