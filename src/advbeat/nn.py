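"""Reverse-mode automatic differentiation and neural layers on NumPy.

A small tape-based engine in float64: each `Tensor` records its parents
and a closure that accumulates gradients, and `Tensor.backward()` walks
the tape in reverse topological order. The op set is exactly what the
beat-classification network needs — broadcast arithmetic, matmul,
dilated/strided 1-D convolution (im2col), batch normalisation, average
pooling with ceil semantics, reductions, sigmoid/ReLU gates, softmax
cross-entropy, and a gradient-reversal identity for adversarial
training. Every op's gradient is validated against central differences
in the test suite.

Layers follow the conv -> batch norm -> ReLU convention, with He-uniform
weight initialisation and zero biases, all seeded through a
`numpy.random.Generator`.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- introspection ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph --------------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; the graph can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / other.data**2, other.data.shape))
        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bw
        return out

    # -- shape --------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))
        out._backward = bw
        return out

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == data)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # ties share grad
        out_data = data if keepdims else np.squeeze(data, axis=axis)
        out = Tensor(out_data, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g)
        out._backward = bw
        return out

    # -- elementwise gates --------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))
        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        offs = np.cumsum([0] + sizes)
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])
    out._backward = bw
    return out


def pad_channels(x: Tensor, n_extra: int) -> Tensor:
    """Zero-pad the channel axis of an (N, C, W) tensor by `n_extra`."""
    if n_extra == 0:
        return x
    n, c, w = x.data.shape
    out = Tensor(np.concatenate(
        [x.data, np.zeros((n, n_extra, w))], axis=1), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g[:, :c, :])
    out._backward = bw
    return out


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity forward; backward multiplies the gradient by -lam."""
    out = Tensor(x.data, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(-lam * g)
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution / pooling ops
# ---------------------------------------------------------------------------


def _conv1d_geometry(w: int, k: int, stride: int, dilation: int, padding: str):
    span = (k - 1) * dilation + 1
    if padding == "valid":
        pl = pr = 0
        w_out = (w - span) // stride + 1
    elif padding == "same":
        w_out = -(-w // stride)  # ceil
        total = max((w_out - 1) * stride + span - w, 0)
        pl = total // 2
        pr = total - pl
    else:
        raise ValueError(f"unknown padding {padding!r}")
    if w_out < 1:
        raise ValueError("convolution input too short")
    return pl, pr, w_out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor,
           stride: int = 1, dilation: int = 1, padding: str = "same") -> Tensor:
    """1-D convolution (cross-correlation): (N,Cin,W) -> (N,Cout,Wout)."""
    n, cin, w = x.data.shape
    cout, cin_w, k = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    pl, pr, w_out = _conv1d_geometry(w, k, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    idx = (np.arange(w_out)[None, :] * stride
           + np.arange(k)[:, None] * dilation)  # (k, w_out)
    cols = np.ascontiguousarray(xp[:, :, idx]).reshape(n, cin * k, w_out)
    w_mat = weight.data.reshape(cout, cin * k)
    out_data = np.matmul(w_mat, cols) + bias.data[None, :, None]
    out = Tensor(out_data, parents=(x, weight, bias))

    def bw(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            # sum_n g[n] @ cols[n].T
            dw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(cout, cin, k))
        if x.requires_grad:
            dcols = np.matmul(w_mat.T, g).reshape(n, cin, k, w_out)
            dxp = np.zeros_like(xp)
            # per-tap positions are distinct strided slices -> no collisions
            for j in range(k):
                start = j * dilation
                dxp[:, :, start: start + stride * w_out: stride] += dcols[:, :, j, :]
            x._accumulate(dxp[:, :, pl: pl + w])
    out._backward = bw
    return out


def avg_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """Average pooling with ceil output length; partial windows average
    over the samples actually present (no padding contribution)."""
    n, c, w = x.data.shape
    w_out = -(-w // stride)
    out_data = np.empty((n, c, w_out))
    counts = np.empty(w_out, dtype=np.int64)
    for i in range(w_out):
        a, b = i * stride, min(i * stride + kernel, w)
        counts[i] = b - a
        out_data[:, :, i] = x.data[:, :, a:b].mean(axis=2)
    out = Tensor(out_data, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for i in range(w_out):
            a, b = i * stride, min(i * stride + kernel, w)
            dx[:, :, a:b] += g[:, :, i:i + 1] / counts[i]
        x._accumulate(dx)
    out._backward = bw
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, C, W), statistics per channel.

    In training mode the batch statistics are used and the running
    buffers updated in place; in eval mode the running buffers are used.
    """
    if training:
        mu = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        m = x.data.shape[0] * x.data.shape[2]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None]) * inv_std[None, :, None]
    out_data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]
    out = Tensor(out_data, parents=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2)))
        if not x.requires_grad:
            return
        if training:
            m = g.shape[0] * g.shape[2]
            gmean = g.mean(axis=(0, 2))[None, :, None]
            gx = (g * xhat).mean(axis=(0, 2))[None, :, None]
            dx = (gamma.data[None, :, None] * inv_std[None, :, None]
                  * (g - gmean - xhat * gx))
            del m
        else:
            dx = gamma.data[None, :, None] * inv_std[None, :, None] * g
        x._accumulate(dx)
    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits)."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        if not logits.requires_grad:
            return
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)
    out._backward = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain-NumPy softmax along the last axis (for prediction paths)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool) -> None:
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
               fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 dilation: int = 1, padding: str = "same"):
        self.weight = Parameter(he_uniform(rng, (cout, cin, kernel), cin * kernel))
        self.bias = Parameter(np.zeros(cout))
        self.stride, self.dilation, self.padding = stride, dilation, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride,
                      self.dilation, self.padding)


class Dense(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.weight = Parameter(he_uniform(rng, (nin, nout), nin))
        self.bias = Parameter(np.zeros(nout))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training, self.momentum,
                          self.eps)


class Adam:
    """Adaptive-moment optimiser; `lr` is mutable for scheduling."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
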