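"""Minimal NumPy neural-network engine for 1-D spectral regression.

Implements exactly the layer vocabulary needed by the attention CNN in
:mod:`vitispec.mimo`: multi-head self-attention over wavelength positions,
same-padded 1-D convolutions with optional L2 kernel penalties, max pooling,
dropout, dense layers, and an Adam optimizer.  Everything is float32 and
fully deterministic given a :class:`numpy.random.Generator`.

Layers follow a simple protocol: ``forward(x, training, rng)`` caches what
``backward(grad)`` needs, ``backward`` accumulates parameter gradients in
``layer.grads`` and returns the gradient w.r.t. the layer input.  Parameter
gradients are *overwritten* per backward call (no accumulation across
batches), matching one optimizer step per mini-batch.

A note on the attention implementation: queries, keys and values are linear
projections (no bias) of the D-dimensional per-wavelength feature vector.
Because D is tiny (3 input channels), scores are computed through the
D x D matrices M_h = Wq_h Wk_h^T and the value/output path through
U_h = Wv_h Wo_h, which cuts the dominant L x L x head_dim contractions to
L x L x D and makes CPU training at L = 216 practical.  The parametrization
(and therefore initialization, optimization and capacity) remains the
standard 8-head, 64-dimensional one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax_lastaxis(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer; subclasses fill ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def penalty(self) -> float:
        """L2 penalty contribution to the loss (0 unless overridden)."""
        return 0.0


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention over sequence positions.

    Input (N, L, D) -> output (N, L, D); attention weights have shape
    (N, heads, L, L) and are softmax-normalized over the key axis.  The last
    forward pass's weights are kept in ``self.attention`` for inspection.
    """

    def __init__(self, d: int, heads: int, head_dim: int, rng: np.random.Generator):
        super().__init__()
        self.d, self.heads, self.head_dim = d, heads, head_dim
        self.scale = 1.0 / np.sqrt(head_dim)
        proj = heads * head_dim
        self.params = {
            "Wq": glorot_uniform(rng, (d, heads, head_dim), d, proj),
            "Wk": glorot_uniform(rng, (d, heads, head_dim), d, proj),
            "Wv": glorot_uniform(rng, (d, heads, head_dim), d, proj),
            "Wo": glorot_uniform(rng, (heads, head_dim, d), proj, d),
            # query-projection bias: its interaction with the keys adds a
            # learnable per-key salience to the scores.  The key bias only
            # shifts whole softmax rows (no effect) and the value bias is a
            # constant output offset absorbed by bo, so those are omitted.
            "bq": np.zeros((heads, head_dim), dtype=DTYPE),
            "bo": np.zeros(d, dtype=DTYPE),
        }
        self.attention: Optional[np.ndarray] = None

    def forward(self, x, training, rng):
        # Queries/keys enter the scores only through M[h] = Wq_h Wk_h^T and
        # values/outputs through U[h] = Wv_h Wo_h (both d x d); with d = 3
        # channels this keeps every L x L contraction at inner dimension d.
        p = self.params
        N, L, d = x.shape
        H = self.heads
        M = np.einsum("dhk,ehk->hde", p["Wq"], p["Wk"])
        U = np.einsum("dhv,hve->hde", p["Wv"], p["Wo"])
        # xm[n,h,l,e] = sum_d x[n,l,d] M[h,d,e]
        xm = (x.reshape(N * L, d) @ M.transpose(1, 0, 2).reshape(d, H * d))
        xm = np.ascontiguousarray(
            xm.reshape(N, L, H, d).transpose(0, 2, 1, 3)
        )
        xT = x[:, None].transpose(0, 1, 3, 2)  # (N, 1, d, L)
        scores = np.matmul(xm, xT)
        # per-key salience from the query bias: bq_h . (x_m Wk_h)
        v = np.einsum("dhk,hk->hd", p["Wk"], p["bq"])  # (H, d)
        sal = np.einsum("nmd,hd->nhm", x, v)
        scores += sal[:, :, None, :]
        scores *= self.scale
        # in-place softmax over the key axis (the (N,H,L,L) tensors dominate
        # memory traffic; avoid fresh allocations on them)
        np.subtract(scores, scores.max(axis=-1, keepdims=True), out=scores)
        np.exp(scores, out=scores)
        scores /= scores.sum(axis=-1, keepdims=True)
        A = scores
        ax = np.matmul(A, x[:, None])  # (N, H, L, d)
        out = (
            ax.transpose(0, 2, 1, 3).reshape(N, L, H * d)
            @ U.reshape(H * d, d)
        )
        out += p["bo"]
        self.attention = A
        self._cache = (x, M, U, xm, A, ax, v)
        return out

    def backward(self, grad):
        x, M, U, xm, A, ax, v = self._cache
        p = self.params
        N, L, d = x.shape
        H = self.heads
        # dU[h,d,e] = sum_{n,l} ax[n,h,l,d] grad[n,l,e]
        dU = (
            ax.transpose(1, 3, 0, 2).reshape(H * d, N * L)
            @ grad.reshape(N * L, d)
        ).reshape(H, d, d)
        # d_ax[n,h,l,d] = sum_e grad[n,l,e] U[h,d,e]
        d_ax = np.ascontiguousarray(
            (grad.reshape(N * L, d) @ U.transpose(2, 0, 1).reshape(d, H * d))
            .reshape(N, L, H, d)
            .transpose(0, 2, 1, 3)
        )
        dA = np.matmul(d_ax, x[:, None].transpose(0, 1, 3, 2))
        # dx via A^T: dx[n,m,e] = sum_{h,l} A[n,h,l,m] d_ax[n,h,l,e]
        dx = np.matmul(A.transpose(0, 1, 3, 2), d_ax).sum(axis=1)
        # softmax backward over the key axis, in place, then score scaling
        rowdot = np.einsum("nhlm,nhlm->nhl", dA, A, optimize=True)
        np.subtract(dA, rowdot[..., None], out=dA)
        np.multiply(dA, A, out=dA)
        dA *= self.scale
        dS = dA
        d_xm = np.matmul(dS, x[:, None])  # (N, H, L, d)
        # dx via scores' key argument: sum_{h,l} dS[n,h,l,m] xm[n,h,l,e]
        dx += np.matmul(dS.transpose(0, 1, 3, 2), xm).sum(axis=1)
        # dx via scores' query argument: sum_{h,e} d_xm[n,h,l,e] M[h,d,e]
        dx += (
            d_xm.transpose(0, 2, 1, 3).reshape(N * L, H * d)
            @ M.transpose(0, 2, 1).reshape(H * d, d)
        ).reshape(N, L, d)
        # dM[h,d,e] = sum_{n,l} x[n,l,d] d_xm[n,h,l,e]
        dM = np.matmul(
            x.reshape(N * L, d).T[None],
            d_xm.transpose(1, 0, 2, 3).reshape(H, N * L, d),
        )
        # salience path: dS summed over queries feeds x and bq/Wk
        dsal = dS.sum(axis=2)  # (N, H, L)
        dx += np.einsum("nhm,hd->nmd", dsal, v)
        dv = np.einsum("nhm,nmd->hd", dsal, x)
        self.grads = {
            "Wq": np.einsum("hde,ehk->dhk", dM, p["Wk"]),
            "Wk": np.einsum("hde,dhk->ehk", dM, p["Wq"])
            + np.einsum("hd,hk->dhk", dv, p["bq"]),
            "bq": np.einsum("hd,dhk->hk", dv, p["Wk"]),
            "Wv": np.einsum("hde,hve->dhv", dU, p["Wo"]),
            "Wo": np.einsum("hde,dhv->hve", dU, p["Wv"]),
            "bo": grad.sum(axis=(0, 1)),
        }
        return dx

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Attention tensor (N, heads, L, L) for input x (inference mode)."""
        self.forward(x.astype(DTYPE), training=False, rng=None)
        return self.attention


class Conv1D(Layer):
    """Same-padded stride-1 1-D convolution with optional ReLU and L2."""

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: int,
        rng: np.random.Generator,
        activation: str = "relu",
        l2: float = 0.0,
    ):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel, self.in_channels, self.filters = kernel, in_channels, filters
        self.pad = (kernel - 1) // 2
        self.activation = activation
        self.l2 = l2
        fan_in = kernel * in_channels
        self.params = {
            "W": glorot_uniform(rng, (fan_in, filters), fan_in, filters),
            "b": np.zeros(filters, dtype=DTYPE),
        }

    def _patches(self, xp: np.ndarray, L: int) -> np.ndarray:
        windows = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=1
        )  # (N, L, C, k)
        return windows.transpose(0, 1, 3, 2).reshape(xp.shape[0], L, -1)

    def forward(self, x, training, rng):
        N, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        patches = self._patches(xp, L)  # (N, L, k*C)
        z = patches @ self.params["W"] + self.params["b"]
        out = relu(z) if self.activation == "relu" else z
        self._cache = (patches, z, L)
        return out

    def backward(self, grad):
        patches, z, L = self._cache
        if self.activation == "relu":
            grad = grad * (z > 0)
        W = self.params["W"]
        f = patches.shape[-1]
        dW = patches.reshape(-1, f).T @ grad.reshape(-1, grad.shape[-1])
        if self.l2:
            dW = dW + 2.0 * self.l2 * W
        self.grads = {"W": dW, "b": grad.sum(axis=(0, 1))}
        dpatch = (grad @ W.T).reshape(
            grad.shape[0], L, self.kernel, self.in_channels
        )
        dxp = np.zeros(
            (grad.shape[0], L + 2 * self.pad, self.in_channels), dtype=DTYPE
        )
        for j in range(self.kernel):
            dxp[:, j : j + L] += dpatch[:, :, j]
        return dxp[:, self.pad : self.pad + L]

    def penalty(self) -> float:
        return float(self.l2 * np.sum(self.params["W"].astype(np.float64) ** 2))


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        N, L, C = x.shape
        Lout = L // self.pool
        xt = x[:, : Lout * self.pool].reshape(N, Lout, self.pool, C)
        arg = xt.argmax(axis=2)
        out = np.take_along_axis(xt, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (arg, x.shape, Lout)
        return out

    def backward(self, grad):
        arg, shape, Lout = self._cache
        N, L, C = shape
        dxt = np.zeros((N, Lout, self.pool, C), dtype=DTYPE)
        np.put_along_axis(dxt, arg[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(shape, dtype=DTYPE)
        dx[:, : Lout * self.pool] = dxt.reshape(N, Lout * self.pool, C)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        units: int,
        rng: np.random.Generator,
        activation: str = "relu",
    ):
        super().__init__()
        self.activation = activation
        self.params = {
            "W": glorot_uniform(rng, (in_features, units), in_features, units),
            "b": np.zeros(units, dtype=DTYPE),
        }

    def forward(self, x, training, rng):
        z = x @ self.params["W"] + self.params["b"]
        out = relu(z) if self.activation == "relu" else z
        self._cache = (x, z)
        return out

    def backward(self, grad):
        x, z = self._cache
        if self.activation == "relu":
            grad = grad * (z > 0)
        self.grads = {"W": x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T


@dataclass
class Adam:
    """Adam optimizer with the standard defaults (lr as configured)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    _state: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, layers: list[Layer]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.learning_rate * np.sqrt(1 - b2**self._t) / (1 - b1**self._t)
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                if key not in self._state:
                    self._state[key] = (
                        np.zeros_like(p, dtype=DTYPE),
                        np.zeros_like(p, dtype=DTYPE),
                    )
                m, v = self._state[key]
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(DTYPE)


class Sequential:
    """A plain layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        out = x.astype(DTYPE)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def penalty(self) -> float:
        return sum(layer.penalty() for layer in self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = w[k]
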