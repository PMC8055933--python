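"""Minimal neural-network layers with hand-written backpropagation.

Everything here operates on plain NumPy arrays.  The layers are sized for
small fixed-shape 3D patches (e.g. 5x5x5), where convolution reduces to a
batched GEMM after an im2col gather — the fastest formulation on one CPU at
this scale.  The per-contrast encoders of the attention network are
*grouped*: a leading group axis G carries all contrasts through one batched
matmul per layer instead of a Python loop, with independent parameters per
group.  Layouts are channels-last throughout: grouped activations are
(G, N, S, C) with S the flattened spatial size.

Each layer caches what its backward pass needs; gradients are accumulated
into per-layer ``grads`` dicts and consumed by :class:`AdamW`.  The backward
passes are verified against central finite differences in the test suite,
so treat any edit here as gradient-breaking until re-checked.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GroupedLinear",
    "GroupedConv3dSame",
    "GroupedBatchNorm",
    "Linear",
    "ELU",
    "AdamW",
    "fan_in_uniform",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    """Base: parameter/gradient bookkeeping shared by all layers."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _init_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


class Linear(Layer):
    """Affine map on the last axis; input may have any leading shape."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.params["W"] = fan_in_uniform(rng, (d_in, d_out), d_in, dtype)
        self.params["b"] = fan_in_uniform(rng, (d_out,), d_in, dtype)
        self._init_grads()
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"] += x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        self.grads["b"] += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.params["W"].T


class GroupedLinear(Layer):
    """G independent affine maps, batched: (G, N, d_in) -> (G, N, d_out)."""

    def __init__(self, groups: int, d_in: int, d_out: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.params["W"] = fan_in_uniform(rng, (groups, d_in, d_out), d_in, dtype)
        self.params["b"] = fan_in_uniform(rng, (groups, 1, d_out), d_in, dtype)
        self._init_grads()
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.matmul(x, self.params["W"]) + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"] += np.matmul(x.transpose(0, 2, 1), dout)
        self.grads["b"] += dout.sum(axis=1, keepdims=True)
        return np.matmul(dout, self.params["W"].transpose(0, 2, 1))


def _conv_indices(shape: tuple[int, int, int], kernel: int):
    """Gather indices for same-padded 3D correlation on a fixed spatial shape.

    Returns (inner, gather, padded_size): ``inner`` scatters the flat volume
    into the zero-padded flat volume; ``gather[s, k]`` indexes the padded flat
    volume for output voxel s and kernel tap k (k in row-major kernel order).
    """
    m = (kernel - 1) // 2
    pz, py, px = (d + 2 * m for d in shape)
    grid = np.stack(np.meshgrid(*[np.arange(d) for d in shape], indexing="ij"), axis=-1)
    vox = grid.reshape(-1, 3)  # (S, 3)
    inner = np.ravel_multi_index((vox[:, 0] + m, vox[:, 1] + m, vox[:, 2] + m), (pz, py, px))
    offs = np.stack(np.meshgrid(*[np.arange(kernel)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
    nb = vox[:, None, :] + offs[None, :, :]  # (S, K3, 3) in padded coords
    gather = np.ravel_multi_index((nb[..., 0], nb[..., 1], nb[..., 2]), (pz, py, px))
    return inner.astype(np.intp), gather.astype(np.intp), pz * py * px


class GroupedConv3dSame(Layer):
    """G independent 3D correlations with 'same' zero padding, batched.

    Activations: (G, N, S, channels), channels last, S the flattened spatial
    size of a fixed ``spatial_shape``.  Weights: (G, K^3 * C_in, C_out) with
    rows ordered kernel-tap-major then input channel, matching the im2col
    column order, so each group's convolution is one slice of a batched GEMM.
    """

    def __init__(self, groups: int, c_in: int, c_out: int, kernel: int,
                 spatial_shape: tuple[int, int, int],
                 rng: np.random.Generator, dtype=np.float32,
                 need_input_grad: bool = True):
        super().__init__()
        self.groups, self.c_in, self.c_out, self.kernel = groups, c_in, c_out, kernel
        self.shape = tuple(spatial_shape)
        self.S = int(np.prod(spatial_shape))
        self.need_input_grad = need_input_grad
        self._inner, self._gather, self._padded = _conv_indices(self.shape, kernel)
        self._k3 = kernel ** 3
        # flat gather indices into (padded * channels); np.take along a flat
        # axis returns a C-contiguous result, unlike a fancy index sandwiched
        # between slices.
        self._flat_idx = {
            ch: (self._gather[:, :, None] * ch + np.arange(ch)).ravel()
            for ch in {c_in, c_out}
        }
        fan_in = c_in * self._k3
        self.params["W"] = fan_in_uniform(rng, (groups, fan_in, c_out), fan_in, dtype)
        self.params["b"] = fan_in_uniform(rng, (groups, 1, c_out), fan_in, dtype)
        self._init_grads()
        self._cols = None

    def _im2col_group(self, xg: np.ndarray, channels: int) -> np.ndarray:
        # xg: (N, S, C) -> (N*S, K3*C); one group at a time so the column
        # matrix stays cache-resident (the all-groups variant thrashes L3)
        n = xg.shape[0]
        xpad = np.zeros((n, self._padded, channels), dtype=xg.dtype)
        xpad[:, self._inner, :] = xg
        cols = np.take(xpad.reshape(n, self._padded * channels),
                       self._flat_idx[channels], axis=1)
        return cols.reshape(n * self.S, self._k3 * channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        g, n = x.shape[:2]
        W, b = self.params["W"], self.params["b"]
        y = np.empty((g, n * self.S, self.c_out), dtype=x.dtype)
        self._cols = []
        for i in range(g):
            cols = self._im2col_group(x[i], self.c_in)
            self._cols.append(cols)
            np.matmul(cols, W[i], out=y[i])
        y += b
        return y.reshape(g, n, self.S, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        g, n = dout.shape[:2]
        d = dout.reshape(g, n * self.S, self.c_out)
        dW, db = self.grads["W"], self.grads["b"]
        db += d.sum(axis=1, keepdims=True)
        if self.need_input_grad:
            W4 = self.params["W"].reshape(g, self._k3, self.c_in, self.c_out)
            Wt = np.ascontiguousarray(W4[:, ::-1].transpose(0, 1, 3, 2)).reshape(
                g, self._k3 * self.c_out, self.c_in)
            dx = np.empty((g, n * self.S, self.c_in), dtype=dout.dtype)
        for i in range(g):
            dW[i] += self._cols[i].T @ d[i]
            if self.need_input_grad:
                # dx = same-padded correlation of dout with the spatially
                # flipped, channel-transposed kernel -- another im2col GEMM.
                np.matmul(self._im2col_group(dout[i], self.c_out), Wt[i], out=dx[i])
        self._cols = None
        if not self.need_input_grad:
            return None
        return dx.reshape(g, n, self.S, self.c_in)


class ELU(Layer):
    """Exponential linear unit, alpha = 1 (shape-agnostic, stateless)."""

    def __init__(self):
        super().__init__()
        self._y = None
        self._pos = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pos = x > 0
        y = np.minimum(x, 0.0)
        np.expm1(y, out=y)
        np.copyto(y, x, where=pos)
        self._y, self._pos = y, pos
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = self._y + 1.0
        np.multiply(dout, g, out=g)
        np.copyto(g, dout, where=self._pos)
        return g


class GroupedBatchNorm(Layer):
    """Per-(group, channel) batch normalization over (batch, spatial).

    Input layout (G, N, S, C).  Training mode uses batch statistics and
    updates exponential running estimates; evaluation mode uses the running
    estimates, which makes inference deterministic.
    """

    def __init__(self, groups: int, channels: int, dtype=np.float32,
                 eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        shape = (groups, 1, 1, channels)
        self.params["gamma"] = np.ones(shape, dtype=dtype)
        self.params["beta"] = np.zeros(shape, dtype=dtype)
        self._init_grads()
        self.running_mean = np.zeros(shape, dtype=dtype)
        self.running_var = np.ones(shape, dtype=dtype)
        self._xhat = None
        self._inv_std = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(1, 2), keepdims=True)
            var = x.var(axis=(1, 2), keepdims=True)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = x - mu
        xhat *= inv_std
        self._xhat, self._inv_std, self._training = xhat, inv_std, training
        out = xhat * self.params["gamma"]
        out += self.params["beta"]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.grads["gamma"] += (dout * xhat).sum(axis=(1, 2), keepdims=True)
        self.grads["beta"] += dout.sum(axis=(1, 2), keepdims=True)
        g = self.params["gamma"]
        if not self._training:
            return dout * (g * inv_std)
        dxhat = dout * g
        mean_d = dxhat.mean(axis=(1, 2), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        dx = xhat * mean_dx
        np.subtract(dxhat, dx, out=dx)
        dx -= mean_d
        dx *= inv_std
        return dx


class AdamW:
    """Adam with decoupled weight decay.

    The decay term is applied directly to the weights, scaled by the learning
    rate, independently of the adaptive gradient step.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p -= (self.lr * update + self.lr * self.weight_decay * p).astype(p.dtype)
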