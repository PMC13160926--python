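"""Minimal reverse-mode tensor engine powering avisep's neural components.

The separation and counting networks in this package are small enough to train
on a single CPU core, so they run on this self-contained NumPy autodiff core
instead of a heavyweight deep-learning framework.  The design is the classic
tape: every :class:`Tensor` remembers its parents and a closure that routes the
incoming gradient to them; ``backward`` walks the tape in reverse topological
order.  All arithmetic is float64 for bit-reproducible runs under a fixed seed.

Only the operations the avisep models need are provided: broadcasting
arithmetic, matmul, pointwise nonlinearities, reductions, reshaping, framing /
overlap-add (the 1-D analysis and synthesis transforms), dilated 2-D
convolution (counter branches) and a stable softmax cross-entropy.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "Adam",
    "concat",
    "stack",
    "sigmoid",
    "tanh",
    "relu",
    "frame",
    "overlap_add",
    "elman_scan",
    "cross_entropy",
    "clip_grad_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs from RNN unrolls are deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(self.data ** e, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = backward
        return out

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        ref = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == ref)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly

        out = Tensor(out_data, parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g)

        out._backward = backward
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._backward = backward
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * out_data * (1.0 - out_data))

    out._backward = backward
    return out


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * (1.0 - out_data * out_data))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    out = Tensor(x.data * mask, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = backward
    return out


def _frame_indices(length: int, kernel: int, stride: int) -> np.ndarray:
    n_frames = (length - kernel) // stride + 1
    return np.arange(n_frames)[:, None] * stride + np.arange(kernel)[None, :]


def _scatter_frames(frames_data: np.ndarray, stride: int, length: int) -> np.ndarray:
    """Sum overlapping frames (..., T, K) back onto a (..., length) signal."""
    *lead, n_frames, kernel = frames_data.shape
    out = np.zeros((*lead, length))
    if kernel % stride == 0:
        # 50%-style overlap: each intra-frame sub-block lands contiguously
        for j in range(kernel // stride):
            seg = frames_data[..., :, j * stride:(j + 1) * stride]
            out[..., j * stride:j * stride + n_frames * stride] += seg.reshape(
                *lead, n_frames * stride)
    else:
        idx = _frame_indices(length, kernel, stride)
        flat = out.reshape(-1, length)
        gflat = frames_data.reshape(-1, n_frames * kernel)
        np.add.at(flat, (np.arange(flat.shape[0])[:, None], idx.ravel()[None, :]), gflat)
    return out


def frame(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Slice the last axis into overlapping frames: (..., L) -> (..., T, K)."""
    length = x.data.shape[-1]
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    idx = _frame_indices(length, kernel, stride)
    out = Tensor(x.data[..., idx], parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(_scatter_frames(g, stride, length))

    out._backward = backward
    return out


def overlap_add(frames: Tensor, stride: int, length: int | None = None) -> Tensor:
    """Inverse of :func:`frame`: (..., T, K) -> (..., (T-1)*stride + K)."""
    *lead, n_frames, kernel = frames.data.shape
    full_len = (n_frames - 1) * stride + kernel
    idx = _frame_indices(full_len, kernel, stride)
    out_data = _scatter_frames(frames.data, stride, full_len)
    if length is not None:
        out_data = out_data[..., :length]

    out = Tensor(out_data, parents=(frames,))

    def backward(g):
        if not frames.requires_grad:
            return
        if length is not None and length < full_len:
            g = np.concatenate(
                [g, np.zeros((*g.shape[:-1], full_len - length))], axis=-1
            )
        frames._accum(g[..., idx].reshape(frames.data.shape))

    out._backward = backward
    return out


def elman_scan(xs: Tensor, wh: Tensor) -> Tensor:
    """Fused Elman recurrence: h_t = tanh(xs_t + h_{t-1} @ wh).

    ``xs`` (B, L, H) already carries the input projection and bias; the
    backward pass is hand-coded truncated-free BPTT, which keeps the tape
    short for long unrolls.
    """
    B, L, H = xs.data.shape
    hs = np.empty((B, L, H))
    h = np.zeros((B, H))
    whd = wh.data
    for t in range(L):
        h = np.tanh(xs.data[:, t, :] + h @ whd)
        hs[:, t, :] = h

    out = Tensor(hs, parents=(xs, wh))

    def backward(g):
        gxs = np.empty_like(hs) if xs.requires_grad else None
        gwh = np.zeros_like(whd) if wh.requires_grad else None
        carry = np.zeros((B, H))
        wht = whd.T
        for t in range(L - 1, -1, -1):
            dtot = (g[:, t, :] + carry) * (1.0 - hs[:, t, :] ** 2)
            if gxs is not None:
                gxs[:, t, :] = dtot
            if gwh is not None and t > 0:
                gwh += hs[:, t - 1, :].T @ dtot
            carry = dtot @ wht
        if gxs is not None:
            xs._accum(gxs)
        if gwh is not None:
            wh._accum(gwh)

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))
    out = Tensor(loss, parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / n)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny parameter container with recursive discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr


def _collect(value) -> Iterable[Parameter]:
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / math.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalize over the last axis with learned gain and bias."""

    def __init__(self, width: int, eps: float = 1e-6):
        self.gain = Parameter(np.ones(width))
        self.bias = Parameter(np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gain + self.bias


class Conv2d(Module):
    """Same-padded 2-D convolution with optional dilation, via explicit gather.

    Input (B, C, H, W); weight (C_out, C_in, kh, kw).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1):
        scale = 1.0 / math.sqrt(c_in * kernel * kernel)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.kernel = kernel
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        k, d = self.kernel, self.dilation
        pad = (k // 2) * d
        B, C, H, W = x.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        offs = (np.arange(k) - k // 2) * d + pad
        hi = (np.arange(H)[:, None] + offs[None, :])  # (H, k)
        wi = (np.arange(W)[:, None] + offs[None, :])  # (W, k)
        # cols: (B, C, k, k, H, W)
        cols = xp[:, :, hi[:, :, None, None], wi[None, None, :, :]]
        cols = cols.transpose(0, 1, 3, 5, 2, 4)  # fancy-index result -> (B,C,H,k,W,k)->fix
        # after fancy indexing: xp[:, :, A, B2] with A (H,k,1,1), B2 (1,1,W,k)
        # result shape (B, C, H, k, W, k); transpose to (B, C, k, k, H, W)
        weight, bias = self.weight, self.bias
        w = weight.data.reshape(weight.data.shape[0], -1)  # (O, C*k*k)
        cols_mat = cols.reshape(B, C * k * k, H * W)
        out_data = np.einsum("of,bfp->bop", w, cols_mat) + bias.data[None, :, None]
        out_data = out_data.reshape(B, -1, H, W)

        out = Tensor(out_data, parents=(x, weight, bias))

        def backward(g):
            gmat = g.reshape(B, g.shape[1], H * W)  # (B, O, P)
            if weight.requires_grad:
                gw = np.einsum("bop,bfp->of", gmat, cols_mat)
                weight._accum(gw.reshape(weight.data.shape))
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.einsum("of,bop->bfp", w, gmat).reshape(B, C, k, k, H, W)
                gcols = gcols.transpose(0, 1, 4, 2, 5, 3)  # back to (B,C,H,k,W,k)
                gxp = np.zeros_like(xp)
                np.add.at(
                    gxp,
                    (slice(None), slice(None), hi[:, :, None, None], wi[None, None, :, :]),
                    gcols,
                )
                x._accum(gxp[:, :, pad:pad + H, pad:pad + W])

        out._backward = backward
        return out


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3):
        self.params = list(params)
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)


def clip_grad_norm(params: Sequence[Parameter], max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
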