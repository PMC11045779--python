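"""Minimal self-contained neural-network stack on NumPy.

Implements exactly the layer types the expression classifier needs — 1D
convolution (valid padding), ReLU, max pooling, inverted dropout, dense
layers and a sigmoid head — with reverse-mode gradients, an Adam optimiser,
and DeepLIFT-style *rescale* multipliers for attribution.

Shapes: sequence tensors are ``(N, L, C)`` (batch, length, channels); dense
tensors are ``(N, D)``.  Parameters are float32 by default; attribution and
gradient checks can run the same network in float64 via :meth:`Network.astype`.

DeepLIFT multipliers satisfy the local summation-to-delta identity
``sum_i m_i * (x_i - ref_i) = y - y_ref`` in every layer: linear layers use
their weights, elementwise nonlinearities the exact secant ratio, and max
pooling routes each pooled delta over its window proportionally to the
squared input deltas (any routing with the correct weighted sum preserves
completeness; this one needs no division by per-element deltas and is exact
even when the pooled argmax differs between input and reference).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "ReLU", "Sigmoid", "MaxPool1D", "Dropout", "Flatten", "Dense",
           "Network", "Adam", "binary_cross_entropy"]


class Layer:
    params: tuple = ()

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, grad_out):
        raise NotImplementedError

    # DeepLIFT rescale -------------------------------------------------
    def forward_pair(self, x, ref):
        """Forward both actual and reference input, caching what the
        multiplier backward pass needs."""
        return self.forward(x), self.forward(ref)

    def multiplier_backward(self, m_out):
        """Propagate DeepLIFT multipliers from output to input."""
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding 1D convolution, kernel stored as (K, C_in, C_out)."""

    def __init__(self, c_in, c_out, kernel_size, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / (kernel_size * c_in))  # He init for ReLU nets
        self.W = (rng.standard_normal((kernel_size, c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.K = kernel_size

    @property
    def params(self):
        return ("W", "b")

    def _im2col(self, x):
        # sliding windows (N, Lo, C, K) flattened to (N*Lo, C*K); the
        # weight matrix is permuted to match, avoiding a transpose copy
        N, L, C = x.shape
        Lo = L - self.K + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.K, axis=1)
        return win.reshape(N * Lo, C * self.K)

    def _wmat(self):
        # (K, C, F) -> (C*K, F) in the _im2col column order
        return np.ascontiguousarray(self.W.transpose(1, 0, 2)).reshape(-1, self.W.shape[2])

    def forward(self, x, train=False, rng=None):
        self._x = x
        N, L, C = x.shape
        Lo = L - self.K + 1
        self._cols = self._im2col(x)
        F = self.W.shape[2]
        y = self._cols @ self._wmat() + self.b
        return y.reshape(N, Lo, F)

    def backward(self, g):
        x = self._x
        N, L, C = x.shape
        Lo = L - self.K + 1
        F = self.W.shape[2]
        gm = g.reshape(N * Lo, F)
        dwm = self._cols.T @ gm  # (C*K, F)
        self.dW = dwm.reshape(C, self.K, F).transpose(1, 0, 2).copy()
        self.db = gm.sum(axis=0)
        dcols = (gm @ self._wmat().T).reshape(N, Lo, C, self.K)
        dx = np.zeros_like(x)
        for k in range(self.K):
            dx[:, k : k + Lo, :] += dcols[:, :, :, k]
        return dx

    def forward_pair(self, x, ref):
        self._pair_shape = x.shape
        return self.forward(x), self.forward(ref)

    def multiplier_backward(self, m_out):
        N, L, C = self._pair_shape
        Lo = L - self.K + 1
        m_in = np.zeros(self._pair_shape, dtype=m_out.dtype)
        for k in range(self.K):
            m_in[:, k : k + Lo, :] += m_out @ self.W[k].T
        return m_in


class Dense(Layer):
    def __init__(self, d_in, d_out, rng, dtype=np.float32, he=True):
        scale = np.sqrt((2.0 if he else 1.0) / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)

    @property
    def params(self):
        return ("W", "b")

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def multiplier_backward(self, m_out):
        return m_out @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def forward_pair(self, x, ref):
        a, ar = np.maximum(x, 0), np.maximum(ref, 0)
        dz = x - ref
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dz != 0, (a - ar) / np.where(dz != 0, dz, 1), 0.0)
        self._ratio = ratio
        return a, ar

    def multiplier_backward(self, m_out):
        return m_out * self._ratio


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)

    def forward_pair(self, x, ref):
        y = 1.0 / (1.0 + np.exp(-x))
        yr = 1.0 / (1.0 + np.exp(-ref))
        dz = x - ref
        self._ratio = np.where(dz != 0, (y - yr) / np.where(dz != 0, dz, 1), 0.0)
        return y, yr

    def multiplier_backward(self, m_out):
        return m_out * self._ratio


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder < pool is dropped."""

    def __init__(self, pool):
        self.pool = pool

    def _windows(self, x):
        N, L, C = x.shape
        Lp = L // self.pool
        return x[:, : Lp * self.pool, :].reshape(N, Lp, self.pool, C), Lp

    def forward(self, x, train=False, rng=None):
        w, Lp = self._windows(x)
        self._arg = w.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(w, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, g):
        N, L, C = self._shape
        Lp = L // self.pool
        gw = np.zeros((N, Lp, self.pool, C), dtype=g.dtype)
        np.put_along_axis(gw, self._arg[:, :, None, :], g[:, :, None, :], axis=2)
        out = np.zeros(self._shape, dtype=g.dtype)
        out[:, : Lp * self.pool, :] = gw.reshape(N, Lp * self.pool, C)
        return out

    def forward_pair(self, x, ref):
        y, yr = self.forward(x), self.forward(ref)
        w, Lp = self._windows(x)
        wr, _ = self._windows(ref)
        dxw = w - wr
        denom = (dxw ** 2).sum(axis=2, keepdims=True)
        dy = (y - yr)[:, :, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            self._route = np.where(denom > 0, dy * dxw / np.where(denom > 0, denom, 1), 0.0)
        self._shape = x.shape
        return y, yr

    def multiplier_backward(self, m_out):
        N, L, C = self._shape
        Lp = L // self.pool
        mw = m_out[:, :, None, :] * self._route
        out = np.zeros(self._shape, dtype=m_out.dtype)
        out[:, : Lp * self.pool, :] = mw.reshape(N, Lp * self.pool, C)
        return out


class BatchNorm(Layer):
    """Per-channel batch normalisation (over batch and length axes for
    sequence tensors).  At inference it is an exact affine map using running
    statistics, so DeepLIFT multipliers propagate through it linearly."""

    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return ("gamma", "beta")

    def forward(self, x, train=False, rng=None):
        C = x.shape[-1]
        xr = x.reshape(-1, C)
        if train:
            mu = xr.mean(axis=0)
            # variance from the second moment: one fused reduction pass
            var = np.einsum("ij,ij->j", xr, xr) / xr.shape[0] - mu * mu
            var = np.maximum(var, 0.0)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        a = (self.gamma * istd).astype(x.dtype)
        self._x, self._mu, self._istd = x, mu, istd
        self._a, self._train = a, train
        return x * a + (self.beta - mu * a).astype(x.dtype)

    def backward(self, g):
        C = g.shape[-1]
        gr = g.reshape(-1, C)
        xr = self._x.reshape(-1, C)
        n = gr.shape[0]
        self.dbeta = gr.sum(axis=0)
        sgx = np.einsum("ij,ij->j", gr, xr)
        self.dgamma = self._istd * (sgx - self._mu * self.dbeta)
        if not self._train:
            return g * self._a
        c2 = self._a * self._istd * self.dgamma / n
        c1 = self._a * self.dbeta / n - c2 * self._mu
        return g * self._a - self._x * c2.astype(g.dtype) - c1.astype(g.dtype)

    def forward_pair(self, x, ref):
        return self.forward(x), self.forward(ref)

    def multiplier_backward(self, m_out):
        return m_out * self.gamma / np.sqrt(self.running_var + self.eps)


class Dropout(Layer):
    def __init__(self, rate):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def forward_pair(self, x, ref):  # identity at inference
        return x, ref

    def multiplier_backward(self, m_out):
        return m_out


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def forward_pair(self, x, ref):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1), ref.reshape(ref.shape[0], -1)

    def multiplier_backward(self, m_out):
        return m_out.reshape(self._shape)


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad_out):
        g = grad_out
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def multipliers(self, x, ref):
        """DeepLIFT rescale multipliers of the final (scalar) output with
        respect to the input, for actual input ``x`` against ``ref``.

        Returns ``(m, y, y_ref)`` with ``m`` shaped like ``x`` and satisfying
        ``sum(m * (x - ref)) = y - y_ref`` per example (float precision).
        """
        a, r = x, ref
        for layer in self.layers:
            a, r = layer.forward_pair(a, r)
        m = np.ones_like(a)
        for layer in reversed(self.layers):
            m = layer.multiplier_backward(m)
        return m, a, r

    # parameter plumbing ------------------------------------------------
    def param_arrays(self):
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer, name))
        return out

    def n_params(self):
        return sum(getattr(l, n).size for l, n in self.param_arrays())

    def _state_arrays(self):
        out = list(self.param_arrays())
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.append((layer, "running_mean"))
                out.append((layer, "running_var"))
        return out

    def get_weights(self):
        return [getattr(l, n).copy() for l, n in self._state_arrays()]

    def set_weights(self, weights):
        for (l, n), w in zip(self._state_arrays(), weights):
            setattr(l, n, w.copy())

    def clear_caches(self):
        """Drop forward-pass scratch arrays (im2col buffers, masks, argmax
        indices).  They are only needed between a forward and its backward;
        clearing them keeps stored/copied networks small."""
        for layer in self.layers:
            for name in [n for n in list(vars(layer)) if n.startswith("_")]:
                delattr(layer, name)

    def astype(self, dtype):
        import copy

        self.clear_caches()
        net = copy.deepcopy(self)
        for layer in net.layers:
            for name, value in vars(layer).items():
                if isinstance(value, np.ndarray) and np.issubdtype(value.dtype,
                                                                   np.floating):
                    setattr(layer, name, value.astype(dtype))
        return net


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-7, matching common
    deep-learning defaults)."""

    def __init__(self, net: Network, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7,
                 weight_decay=0.0):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n in net.param_arrays()]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in net.param_arrays()]

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (l, n) in enumerate(self.net.param_arrays()):
            g = getattr(l, "d" + n)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p = getattr(l, n)
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and n == "W":
                # decoupled weight decay (applied outside the adaptive
                # rescaling; weights only, not biases)
                step = step + self.lr * self.weight_decay * p
            setattr(l, n, p - step.astype(p.dtype))


def binary_cross_entropy(p, y, eps=1e-7):
    """Mean BCE and its gradient with respect to the probabilities."""
    p = np.clip(p, eps, 1 - eps)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    grad = ((p - y) / (p * (1 - p))) / p.size
    return loss, grad.astype(p.dtype)
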