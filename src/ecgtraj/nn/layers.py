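"""Minimal NumPy neural-network layers with explicit reverse-mode gradients.

Every layer is a :class:`Module` caching whatever its backward pass needs.
``forward`` consumes a float32 array and returns one; ``backward`` consumes the
gradient of the loss w.r.t. the output and returns the gradient w.r.t. the
input, accumulating parameter gradients into ``grads`` along the way.  The
design is deliberately small: only the operations needed by the 1D residual
lead encoder and the lead-token transformer exist here.
"""
from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._children: list[tuple[str, "Module"]] = []
        self.training: bool = True

    # -- registry ---------------------------------------------------------
    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.ascontiguousarray(value, dtype=DTYPE)
        self.params[name] = arr
        self.grads[name] = np.zeros_like(arr)
        return arr

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children.append((name, module))
        return module

    def modules(self):
        yield self
        for _, child in self._children:
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name in self.params:
            yield f"{prefix}{name}", self
        for cname, child in self._children:
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def zero_grad(self) -> None:
        for m in self.modules():
            for g in m.grads.values():
                g[...] = 0.0

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for path, mod in self.named_parameters():
            leaf = path.rsplit(".", 1)[-1]
            state[path] = mod.params[leaf].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for path, mod in self.named_parameters():
            leaf = path.rsplit(".", 1)[-1]
            mod.params[leaf][...] = state[path]
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                m.running_mean[...] = state[f"__bn{i}.running_mean"]
                m.running_var[...] = state[f"__bn{i}.running_var"]

    def n_parameters(self) -> int:
        return sum(p.size for m in self.modules() for p in m.params.values())


# -------------------------------------------------------------------------
# convolution stack (channels-last: all conv tensors are (N, T, C))
# -------------------------------------------------------------------------

class Conv1d(Module):
    """1D convolution over the time axis of (N, T, C_in) inputs.

    Channels-last keeps the im2col patch matrix one contiguous copy away from
    a single large GEMM; 1x1 convolutions skip windowing entirely.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = False, *, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        std = np.sqrt(2.0 / (c_in * kernel))
        self.add_param("W", rng.normal(0.0, std, size=(c_in * kernel, c_out)))
        self.use_bias = bias
        if bias:
            self.add_param("b", np.zeros(c_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.k == 1 and self.padding == 0:
            self._x1 = x[:, ::self.stride] if self.stride > 1 else x
            self._t_in = x.shape[1]
            y = self._x1.reshape(-1, self.c_in) @ self.params["W"]
            y = y.reshape(self._x1.shape[0], self._x1.shape[1], self.c_out)
        else:
            if self.padding:
                x = np.pad(x, ((0, 0), (self.padding, self.padding), (0, 0)))
            self._t_pad = x.shape[1]
            win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
            win = win[:, ::self.stride]                   # (N, T_out, C_in, k)
            n, t_out = win.shape[:2]
            col = win.reshape(n, t_out, self.c_in * self.k)   # one copy
            self._col = col
            y = col.reshape(-1, self.c_in * self.k) @ self.params["W"]
            y = y.reshape(n, t_out, self.c_out)
        if self.use_bias:
            y += self.params["b"]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t_out, _ = dy.shape
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        if self.use_bias:
            self.grads["b"] += dy2.sum(axis=0)
        if self.k == 1 and self.padding == 0:
            self.grads["W"] += self._x1.reshape(-1, self.c_in).T @ dy2
            dx1 = (dy2 @ self.params["W"].T).reshape(n, t_out, self.c_in)
            if self.stride == 1:
                return dx1
            dx = np.zeros((n, self._t_in, self.c_in), dtype=DTYPE)
            dx[:, ::self.stride] = dx1
            return dx
        self.grads["W"] += self._col.reshape(-1, self.c_in * self.k).T @ dy2
        dcol = (dy2 @ self.params["W"].T).reshape(n, t_out, self.c_in, self.k)
        dx = np.zeros((n, self._t_pad, self.c_in), dtype=DTYPE)
        for j in range(self.k):
            dx[:, j : j + self.stride * t_out : self.stride] += dcol[:, :, :, j]
        if self.padding:
            dx = dx[:, self.padding:-self.padding]
        return dx


class BatchNorm1d(Module):
    """Per-channel batch norm over (batch, time) for (N, T, C) inputs."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.add_param("gamma", np.ones(c))
        self.add_param("beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean) * inv
        self._xhat, self._inv = xhat, inv
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not self.training:
            return dxhat * inv
        m = dy.shape[0] * dy.shape[1]
        term = dxhat - dxhat.mean(axis=(0, 1), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 1), keepdims=True) / m
        return term * inv


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Module):
    """Max pooling over the time axis of (N, T, C) inputs."""

    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.k, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.padding:
            x = np.pad(x, ((0, 0), (self.padding, self.padding), (0, 0)),
                       constant_values=-np.inf)
        n, t, c = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        win = win[:, ::self.stride]                           # (N, T_out, C, k)
        self._arg = win.argmax(axis=3)
        self._shape = (n, t, win.shape[1], c)
        return win.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t_pad, t_out, c = self._shape
        d4 = np.zeros((n, t_out, c, self.k), dtype=DTYPE)
        np.put_along_axis(d4, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros((n, t_pad, c), dtype=DTYPE)
        for j in range(self.k):
            dx[:, j : j + self.stride * t_out : self.stride] += d4[:, :, :, j]
        if self.padding:
            dx = dx[:, self.padding:-self.padding]
        return dx


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.add_param("W", rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.use_bias = bias
        if bias:
            self.add_param("b", np.zeros(d_out))
        self.d_in, self.d_out = d_in, d_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        x2 = x.reshape(-1, self.d_in)
        self._x2 = x2
        y = x2 @ self.params["W"]
        if self.use_bias:
            y = y + self.params["b"]
        return y.reshape(*self._xshape[:-1], self.d_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy2 = dy.reshape(-1, self.d_out)
        self.grads["W"] += self._x2.T @ dy2
        if self.use_bias:
            self.grads["b"] += dy2.sum(axis=0)
        return (dy2 @ self.params["W"].T).reshape(self._xshape)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.add_param("gamma", np.ones(d))
        self.add_param("beta", np.zeros(d))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat, self._inv = (x - mean) * inv, inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        return inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                      - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self.add_child(str(i), layer)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention; stores the last attention
    weights (batch, heads, L, L) for interpretability."""

    def __init__(self, d: int, n_heads: int, *, rng: np.random.Generator):
        super().__init__()
        if d % n_heads:
            raise ValueError(f"embed dim {d} not divisible by {n_heads} heads")
        self.d, self.h, self.dh = d, n_heads, d // n_heads
        self.wq = self.add_child("wq", Linear(d, d, rng=rng))
        self.wk = self.add_child("wk", Linear(d, d, rng=rng))
        self.wv = self.add_child("wv", Linear(d, d, rng=rng))
        self.wo = self.add_child("wo", Linear(d, d, rng=rng))
        self.last_attn: np.ndarray | None = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, L, _ = x.shape
        return x.reshape(n, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, _ = x.shape
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        self.last_attn = attn
        self._q, self._k, self._v, self._attn = q, k, v, attn
        out = attn @ v                                        # (n, h, L, dh)
        merged = out.transpose(0, 2, 1, 3).reshape(n, L, self.d)
        return self.wo.forward(merged)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, L, _ = dy.shape
        dmerged = self.wo.backward(dy)
        dout = dmerged.reshape(n, L, self.h, self.dh).transpose(0, 2, 1, 3)
        q, k, v, attn = self._q, self._k, self._v, self._attn
        dattn = dout @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dout
        # softmax backward
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q

        def merge(a):
            return a.transpose(0, 2, 1, 3).reshape(n, L, self.d)

        dx = self.wq.backward(merge(dq))
        dx = dx + self.wk.backward(merge(dk))
        dx = dx + self.wv.backward(merge(dv))
        return dx


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + MHA(LN(x)), then x + FFN(LN(x)).

    Pre-norm keeps the residual path unnormalized, which trains stably from
    scratch without a warmup schedule.
    """

    def __init__(self, d: int, n_heads: int, ffn_dim: int, *, rng: np.random.Generator):
        super().__init__()
        self.mha = self.add_child("mha", MultiHeadSelfAttention(d, n_heads, rng=rng))
        self.ln1 = self.add_child("ln1", LayerNorm(d))
        self.fc1 = self.add_child("fc1", Linear(d, ffn_dim, rng=rng))
        self.act = self.add_child("act", ReLU())
        self.fc2 = self.add_child("fc2", Linear(ffn_dim, d, rng=rng))
        self.ln2 = self.add_child("ln2", LayerNorm(d))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x1 = x + self.mha.forward(self.ln1.forward(x))
        return x1 + self.fc2.forward(self.act.forward(self.fc1.forward(
            self.ln2.forward(x1))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        df = self.ln2.backward(self.fc1.backward(self.act.backward(
            self.fc2.backward(dy))))
        dx1 = dy + df
        dmha = self.ln1.backward(self.mha.backward(dx1))
        return dx1 + dmha
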