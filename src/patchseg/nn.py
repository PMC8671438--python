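"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the operations the package's encoder–decoder models and
self-supervised objective need: 2D same-padding convolution, 2×2 max pooling,
2× nearest-neighbor upsampling, channel concatenation, elementwise
relu/sigmoid/log/arithmetic, slicing, axis flips and transposition (for the
augmentation inverse), summation, and an ADAM optimizer. Everything runs in
float64 on the CPU.

Gradients are checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- autograd driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ---- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g, self.data.shape)),
            other._accum(_unbroadcast(g, other.data.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g * other.data, self.data.shape)),
            other._accum(_unbroadcast(g * self.data, other.data.shape)),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bw
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape).copy())
        return out

    def mean(self):
        return self.sum() / self.data.size

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---- nonlinearities ------------------------------------------------------
def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, (x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), (x,))
    out._backward = lambda g: x._accum(g / x.data)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where unclipped."""
    out = Tensor(np.clip(x.data, lo, hi), (x,))
    inside = (x.data > lo) & (x.data < hi)
    out._backward = lambda g: x._accum(g * inside)
    return out


# ---- geometry (augmentation inverse) -------------------------------------
def flip(x: Tensor, axis: int) -> Tensor:
    out = Tensor(np.flip(x.data, axis=axis).copy(), (x,))
    out._backward = lambda g: x._accum(np.flip(g, axis=axis))
    return out


def transpose_last2(x: Tensor) -> Tensor:
    out = Tensor(np.swapaxes(x.data, -2, -1).copy(), (x,))
    out._backward = lambda g: x._accum(np.swapaxes(g, -2, -1))
    return out


# ---- structural ops -------------------------------------------------------
def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bw
    return out


# ---- convolution / pooling / upsampling ----------------------------------
def _conv_raw(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padding correlation of x (N,C,H,W) with w (F,C,kh,kw) via im2col.

    Returns (output (N,F,H,W), cols (N*H*W, C*kh*kw)) — cols is reused for
    the weight gradient.
    """
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * kh * kw)
    out = cols @ w.reshape(f, -1).T
    return out.reshape(n, h, wd, f).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, same-padding 2D convolution (cross-correlation) with bias."""
    n, c, h, wd = x.data.shape
    f, _, kh, kw = w.data.shape
    y, cols = _conv_raw(x.data, w.data)
    out = Tensor(y + b.data[None, :, None, None], (x, w, b))

    def bw(g):
        b._accum(g.sum(axis=(0, 2, 3)))
        g_flat = g.transpose(0, 2, 3, 1).reshape(n * h * wd, f)
        w._accum((cols.T @ g_flat).T.reshape(f, c, kh, kw))
        wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,kh,kw)
        gx, _ = _conv_raw(g, np.ascontiguousarray(wt))
        x._accum(gx)

    out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    m = blocks.max(axis=(3, 5))
    out = Tensor(m, (x,))

    def bw(g):
        mask = blocks == m[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / counts)
        x._accum(gx.reshape(n, c, h, w))

    out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,))
    out._backward = lambda g: x._accum(
        g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
    )
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W) with affine parameters.

    Statistics always come from the current batch; the models here train and
    predict on full batches of patches, so no running-average mode is kept.
    """
    n, c, h, w = x.data.shape
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None],
                 (x, gamma, beta))
    m = n * h * w

    def bw(g):
        beta._accum(g.sum(axis=axes))
        gamma._accum((g * xhat).sum(axis=axes))
        gxhat = g * gamma.data[None, :, None, None]
        # standard batchnorm backward: remove the mean and the xhat-projected
        # components so the gradient respects the normalization constraint
        gx = inv * (gxhat
                    - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True))
        x._accum(gx)

    out._backward = bw
    return out


# ---- optimizer ------------------------------------------------------------
class Adam:
    """Adaptive momentum estimation over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 grad_clip: float | None = None, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.grad_clip = grad_clip
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.grad_clip is not None:
                # near-saturated probabilities inside log terms can spike the
                # gradient by orders of magnitude; clip to keep ADAM's second
                # moment from collapsing the effective step size afterwards
                g = np.clip(g, -self.grad_clip, self.grad_clip)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                # decoupled decay; also the escape route out of a saturated
                # logistic head, where loss gradients vanish exactly
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
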