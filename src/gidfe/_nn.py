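"""Minimal reverse-mode autodiff engine on NumPy arrays.

Provides exactly the primitives the network architecture needs: 2-D
convolution (im2col), batch normalization, max/average pooling, global
average pooling, dense layers, ReLU/sigmoid, elementwise add/multiply,
softmax cross-entropy, and an SGD-with-momentum optimizer with L2
regularization.  Gradients flow to any intermediate activation, which is
what class-activation mapping requires.

All tensors are float32 NCHW.  Every source of randomness is an explicit
``numpy.random.Generator``, so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "global_avg_pool",
    "linear",
    "batch_norm2d",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


class Tensor:
    """A NumPy array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor through its whole graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep residual graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> None:
        for p in self._parents:
            p.zero_graph()
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise ops


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    # clip keeps the output strictly inside (0, 1) at float32 precision,
    # as a gating activation requires; the value error is < 3e-7
    z = np.clip(x.data.astype(np.float64), -15.0, 15.0)
    s = (1.0 / (1.0 + np.exp(-z))).astype(np.float32)

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int, oh: int, ow: int):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv2d(x, weight, bias=None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; weight is (F, C, kh, kw), x is (N, C, H, W)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    f, c, kh, kw = weight.data.shape
    n = x.data.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    w2 = weight.data.reshape(f, c * kh * kw)
    out = np.matmul(w2, cols)  # (N, F, OH*OW)
    if bias is not None:
        bias = _as_tensor(bias)
        out = out + bias.data.reshape(1, f, 1)
    out_data = out.reshape(n, f, oh, ow)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(n, f, oh * ow)
        weight._accumulate(
            np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.data.shape)
        )
        if bias is not None:
            bias._accumulate(g2.sum(axis=(0, 2)))
        dcols = np.matmul(w2.T, g2)  # (N, C*kh*kw, OH*OW)
        x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, pad, oh, ow))

    return _make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# pooling


def max_pool2d(x, size: int, stride: int, pad: int = 0) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    # zero padding; adequate for the post-ReLU maps this layer sees
    cols, oh, ow = _im2col(x.data, size, size, stride, pad)
    cols = cols.reshape(n, c, size * size, oh * ow)
    arg = cols.argmax(axis=2)
    out_data = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :].reshape(n, c, oh, ow)

    def backward(g):
        dcols = np.zeros((n, c, size * size, oh * ow), dtype=np.float32)
        np.put_along_axis(dcols, arg[:, :, None, :], g.reshape(n, c, 1, oh * ow), axis=2)
        x._accumulate(
            _col2im(dcols.reshape(n, c * size * size, oh * ow), x.data.shape, size, size, stride, pad, oh, ow)
        )

    return _make(out_data, (x,), backward)


def avg_pool2d(x, size: int) -> Tensor:
    """Non-overlapping average pooling; spatial dims must divide by `size`."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % size or w % size:
        raise ValueError(f"spatial size ({h},{w}) not divisible by pool size {size}")
    oh, ow = h // size, w // size
    out_data = x.data.reshape(n, c, oh, size, ow, size).mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (size * size), (n, c, oh, size, ow, size)
        ).reshape(n, c, h, w)
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# dense / batch norm


def linear(x, weight, bias) -> Tensor:
    """x (N, D) @ weight (D, K) + bias (K,)."""
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    out_data = x.data @ weight.data + bias.data

    def backward(g):
        x._accumulate(g @ weight.data.T)
        weight._accumulate(x.data.T @ g)
        bias._accumulate(g.sum(axis=0))

    return _make(out_data, (x, weight, bias), backward)


def batch_norm2d(
    x,
    gamma,
    beta,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Channelwise batch normalization; updates running stats in train mode."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    n, c, h, w = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gs = g * gamma.data[None, :, None, None]
        if training:
            m = n * h * w
            dxhat_mean = gs.mean(axis=(0, 2, 3))
            dxhat_xhat_mean = (gs * xhat).mean(axis=(0, 2, 3))
            dx = (
                gs
                - dxhat_mean[None, :, None, None]
                - xhat * dxhat_xhat_mean[None, :, None, None]
            ) * inv_std[None, :, None, None]
        else:
            dx = gs * inv_std[None, :, None, None]
        x._accumulate(dx.astype(np.float32))

    return _make(out_data.astype(np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# loss


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, y: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels y."""
    logits = _as_tensor(logits)
    n = logits.data.shape[0]
    p = softmax(logits.data.astype(np.float64))
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12)))

    def backward(g):
        d = p.copy()
        d[np.arange(n), y] -= 1.0
        logits._accumulate((g * d / n).astype(np.float32))

    return _make(np.float32(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# modules


class Module:
    """Base class: recursive parameter discovery over attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters plus batch-norm statistics."""
        out: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str) -> None:
            for k, v in mod.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[name] = v.data
                elif isinstance(v, np.ndarray):
                    out[name] = v
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        mine = self.state_arrays()
        missing = set(mine) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)[:5]}")
        for k, arr in mine.items():
            src = np.asarray(state[k])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: {src.shape} vs {arr.shape}")
            arr[...] = src


class Conv2d(Module):
    """Convolution layer; He-normal initialization, optionally biased."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = 0.1

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training, momentum=self.momentum)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0.0, scale, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 penalty."""

    def __init__(self, params: list[Tensor], lr: float = 0.01, momentum: float = 0.9,
                 l2: float = 1e-4):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.l2 = l2
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.l2 * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
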