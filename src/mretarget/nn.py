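"""Minimal NumPy neural-network toolkit for the site scorer.

Implements exactly the layer set the five-branch CNN-GRU architecture
needs: valid (unpadded) strided 1-D convolution, batch normalization,
leaky ReLU, non-overlapping max pooling, GRU (full-sequence output with
backpropagation through time), inverted dropout, dense layers, and Adam.

Design notes
------------
* Everything is float64 forward/backward for numerically stable training
  on small datasets; inputs may be float32.
* Layers cache what backward needs on the instance; one forward must be
  followed by at most one backward.
* Inference (``train=False``) uses batch-norm running statistics and skips
  dropout, so scores are independent of batch composition.
* Determinism: all randomness flows through a ``numpy.random.Generator``
  supplied by the caller; no global state is touched.
"""

from __future__ import annotations

import numpy as np

from mretarget.errors import ConfigurationError, ModelError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self):
        """List of (param, grad) array pairs; arrays are updated in place."""
        return []


class Conv1D(Layer):
    """Strided valid 1-D convolution: (B, L, C) -> (B, L_out, filters)."""

    def __init__(self, in_channels, filters, kernel, stride, rng):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.stride = stride
        self.W = _glorot(rng, kernel * in_channels, filters, (kernel * in_channels, filters))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @staticmethod
    def out_length(L: int, kernel: int, stride: int) -> int:
        return (L - kernel) // stride + 1

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=np.float64)
        B, L, C = x.shape
        Lout = self.out_length(L, self.kernel, self.stride)
        if Lout <= 0:
            raise ModelError(
                f"Conv1D kernel {self.kernel} stride {self.stride} on length {L}"
            )
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (B, L-k+1, C, k) -> strided -> (B, Lout, k, C) -> (B, Lout, k*C)
        patches = win[:, :: self.stride].transpose(0, 1, 3, 2).reshape(B, Lout, -1)
        self._patches = patches
        self._in_shape = (B, L, C)
        return patches @ self.W + self.b

    def backward(self, grad):
        B, L, C = self._in_shape
        Lout = grad.shape[1]
        flat = grad.reshape(-1, self.filters)
        self.dW = self._patches.reshape(-1, self.kernel * C).T @ flat
        self.db = flat.sum(axis=0)
        dpatch = (grad @ self.W.T).reshape(B, Lout, self.kernel, C)
        dx = np.zeros((B, L, C))
        for t in range(Lout):
            s = t * self.stride
            dx[:, s : s + self.kernel, :] += dpatch[:, t]
        return dx

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes.

    Works for (B, C) dense activations and (B, L, C) conv activations.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, axes)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, std, axes = self._cache
        m = np.prod([xhat.shape[a] for a in axes])
        self.dgamma = (grad * xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes) / m) / std
        return dx

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class LeakyReLU(Layer):
    def __init__(self, alpha=0.1):
        self.alpha = alpha

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class MaxPool1D(Layer):
    """Non-overlapping max pooling: output length = floor(L / pool)."""

    def __init__(self, pool=2):
        self.pool = pool

    @staticmethod
    def out_length(L: int, pool: int) -> int:
        return L // pool

    def forward(self, x, train):
        B, L, C = x.shape
        Lp = L // self.pool
        if Lp <= 0:
            raise ModelError(f"MaxPool1D pool {self.pool} on length {L}")
        xr = x[:, : Lp * self.pool].reshape(B, Lp, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = (B, L, C)
        return xr.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        Lp = L // self.pool
        dxr = np.zeros((B, Lp, self.pool, C))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, : Lp * self.pool] = dxr.reshape(B, Lp * self.pool, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        if not 0 <= rate < 1:
            raise ConfigurationError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class GRU(Layer):
    """Gated recurrent unit over (B, T, in_dim), returning all hidden states.

    Update convention: h_t = (1 - z_t) * h_{t-1} + z_t * h~_t with
    z = sigma(x Wz + h Uz + bz), r = sigma(x Wr + h Ur + br),
    h~ = tanh(x Wh + (r * h) Uh + bh).
    """

    def __init__(self, in_dim, units, rng):
        self.in_dim, self.units = in_dim, units
        def w(shape, fi, fo):
            return _glorot(rng, fi, fo, shape)
        self.Wz = w((in_dim, units), in_dim, units)
        self.Wr = w((in_dim, units), in_dim, units)
        self.Wh = w((in_dim, units), in_dim, units)
        self.Uz = w((units, units), units, units)
        self.Ur = w((units, units), units, units)
        self.Uh = w((units, units), units, units)
        self.bz = np.zeros(units)
        self.br = np.zeros(units)
        self.bh = np.zeros(units)
        self._zero_grads()

    def _zero_grads(self):
        self.dWz = np.zeros_like(self.Wz); self.dWr = np.zeros_like(self.Wr)
        self.dWh = np.zeros_like(self.Wh); self.dUz = np.zeros_like(self.Uz)
        self.dUr = np.zeros_like(self.Ur); self.dUh = np.zeros_like(self.Uh)
        self.dbz = np.zeros_like(self.bz); self.dbr = np.zeros_like(self.br)
        self.dbh = np.zeros_like(self.bh)

    def forward(self, x, train):
        x = np.asarray(x, dtype=np.float64)
        B, T, _ = x.shape
        h = np.zeros((B, self.units))
        H = np.zeros((B, T, self.units))
        cache = []
        for t in range(T):
            xt = x[:, t]
            z = _sigmoid(xt @ self.Wz + h @ self.Uz + self.bz)
            r = _sigmoid(xt @ self.Wr + h @ self.Ur + self.br)
            hcand = np.tanh(xt @ self.Wh + (r * h) @ self.Uh + self.bh)
            h_new = (1 - z) * h + z * hcand
            cache.append((xt, h, z, r, hcand))
            h = h_new
            H[:, t] = h
        self._cache = cache
        self._x_shape = x.shape
        return H

    def backward(self, grad):
        B, T, _ = self._x_shape
        self._zero_grads()
        dx = np.zeros(self._x_shape)
        dh_next = np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, hcand = self._cache[t]
            dh = grad[:, t] + dh_next
            dz = dh * (hcand - h_prev)
            dhcand = dh * z
            dh_prev = dh * (1 - z)

            da_h = dhcand * (1 - hcand ** 2)
            self.dWh += xt.T @ da_h
            self.dUh += (r * h_prev).T @ da_h
            self.dbh += da_h.sum(axis=0)
            drh = da_h @ self.Uh.T
            dr = drh * h_prev
            dh_prev += drh * r

            da_z = dz * z * (1 - z)
            self.dWz += xt.T @ da_z
            self.dUz += h_prev.T @ da_z
            self.dbz += da_z.sum(axis=0)
            dh_prev += da_z @ self.Uz.T

            da_r = dr * r * (1 - r)
            self.dWr += xt.T @ da_r
            self.dUr += h_prev.T @ da_r
            self.dbr += da_r.sum(axis=0)
            dh_prev += da_r @ self.Ur.T

            dx[:, t] = da_z @ self.Wz.T + da_r @ self.Wr.T + da_h @ self.Wh.T
            dh_next = dh_prev
        return dx

    def params_grads(self):
        return [
            (self.Wz, self.dWz), (self.Wr, self.dWr), (self.Wh, self.dWh),
            (self.Uz, self.dUz), (self.Ur, self.dUr), (self.Uh, self.dUh),
            (self.bz, self.dbz), (self.br, self.dbr), (self.bh, self.dbh),
        ]


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng):
        self.W = _glorot(rng, in_dim, out_dim, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = np.asarray(x, dtype=np.float64)
        return self._x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out


class BranchedNetwork:
    """Named input branches whose flattened outputs feed a shared dense head.

    The final head layer emits one logit per sample; apply a sigmoid for
    probabilities (the loss works on logits for stability).
    """

    def __init__(self, branches: dict[str, Sequential], head: Sequential,
                 branch_widths: dict[str, int]):
        self.branches = branches
        self.head = head
        self.branch_widths = branch_widths  # flattened width per branch

    def forward(self, inputs: dict[str, np.ndarray], train: bool) -> np.ndarray:
        outs = [self.branches[name].forward(inputs[name], train) for name in self.branches]
        concat = np.concatenate(outs, axis=1)
        return self.head.forward(concat, train)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        dconcat = self.head.backward(dlogit[:, None])
        offset = 0
        for name in self.branches:
            w = self.branch_widths[name]
            self.branches[name].backward(dconcat[:, offset : offset + w])
            offset += w

    def params_grads(self):
        out = []
        for name in self.branches:
            out.extend(self.branches[name].params_grads())
        out.extend(self.head.params_grads())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params_grads()]

    def set_weights(self, weights) -> None:
        pairs = self.params_grads()
        if len(weights) != len(pairs):
            raise ModelError(
                f"weight count mismatch: {len(weights)} given, {len(pairs)} expected"
            )
        for (p, _), w in zip(pairs, weights):
            if p.shape != w.shape:
                raise ModelError(f"weight shape mismatch: {w.shape} vs {p.shape}")
            p[...] = w

    def batchnorm_state(self) -> list[np.ndarray]:
        out = []
        for seq in list(self.branches.values()) + [self.head]:
            for layer in seq.layers:
                if isinstance(layer, BatchNorm):
                    out.append(layer.running_mean.copy())
                    out.append(layer.running_var.copy())
        return out

    def set_batchnorm_state(self, state) -> None:
        it = iter(state)
        for seq in list(self.branches.values()) + [self.head]:
            for layer in seq.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean = next(it).copy()
                    layer.running_var = next(it).copy()


class Adam:
    def __init__(self, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params_grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, (p, g) in enumerate(params_grads):
            m = self.m.setdefault(idx, np.zeros_like(p))
            v = self.v.setdefault(idx, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return _sigmoid(np.asarray(x, dtype=np.float64))


def bce_loss_and_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean binary cross-entropy on logits and its gradient d loss / d logit."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = float(-np.mean(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps)))
    grad = (p - labels) / len(labels)
    return loss, grad
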