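"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the gain-modulated convolutional
network: a tape-based tensor type plus the handful of differentiable
operations the architecture needs (convolution via im2col, batch
normalization with a frozen affine transform, max/average pooling,
gain-scaled rectification, dense layers and a fused softmax
cross-entropy). Everything runs in float32 and is deterministic given
the inputs, which is what makes single-seed reproducibility of whole
training runs possible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Tensor", "Parameter", "backward"]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


class Parameter(Tensor):
    """Trainable tensor (leaf node)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _needs_grad(*tensors):
    return any(t.requires_grad for t in tensors)


def backward(loss: Tensor):
    """Backpropagate from a scalar loss through the recorded tape."""
    topo, seen = [], set()

    def visit(t):
        if id(t) in seen:
            return
        seen.add(id(t))
        for p in t._parents:
            visit(p)
        topo.append(t)

    visit(loss)
    loss.grad = np.ones_like(loss.data)
    for t in reversed(topo):
        if t._backward is not None and t.grad is not None:
            t._backward(t.grad)


# ---------------------------------------------------------------------------
# basic ops


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _needs_grad(a, b), (a, b))

    def back(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = back
    return out


def _unbroadcast(g, shape):
    """Sum gradient over broadcast dimensions back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def gain_relu(x: Tensor, gain: float) -> Tensor:
    """Rectified response with multiplicative neural gain: G * max(0, x)."""
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    mask = x.data > 0
    out = Tensor(np.where(mask, gain * x.data, 0.0), x.requires_grad, (x,))

    def back(g):
        if x.requires_grad:
            x.accumulate(np.where(mask, gain * g, 0.0))

    out._backward = back
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), x.requires_grad, (x,))

    def back(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    out._backward = back
    return out


def mean_spatial(x: Tensor) -> Tensor:
    """Global average pool: (N, C, H, W) -> (N, C)."""
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), x.requires_grad, (x,))

    def back(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    out._backward = back
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map: (N, F) @ (F, O) + (O,)."""
    out = Tensor(x.data @ w.data + b.data, _needs_grad(x, w, b), (x, w, b))

    def back(g):
        if x.requires_grad:
            x.accumulate(g @ w.data.T)
        if w.requires_grad:
            w.accumulate(x.data.T @ g)
        if b.requires_grad:
            b.accumulate(g.sum(axis=0))

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# convolution / pooling via strided patch views


def _patches(xp, kh, kw, sh, sw):
    """View of padded input (N,C,Hp,Wp) as (N,OH,OW,C,KH,KW) patches."""
    n, c, hp, wp = xp.shape
    oh = (hp - kh) // sh + 1
    ow = (wp - kw) // sw + 1
    sn, sc, shh, sww = xp.strides
    view = as_strided(
        xp,
        shape=(n, oh, ow, c, kh, kw),
        strides=(sn, shh * sh, sww * sw, sc, shh, sww),
        writeable=False,
    )
    return view, oh, ow


def _conv1x1(x: Tensor, w: Tensor, stride: int) -> Tensor:
    """Pointwise convolution as a channel matmul (fast path)."""
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    wmat = w.data.reshape(o, c)
    out_data = np.einsum("oc,nchw->nohw", wmat, xs, optimize=True)
    out = Tensor(out_data, _needs_grad(x, w), (x, w))

    def back(g):
        if w.requires_grad:
            w.accumulate(np.einsum("nohw,nchw->oc", g, xs, optimize=True).reshape(w.data.shape))
        if x.requires_grad:
            dxs = np.einsum("oc,nohw->nchw", wmat, g, optimize=True)
            if stride > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxs
            else:
                dx = dxs
            x.accumulate(dx)

    out._backward = back
    return out


def conv2d(x: Tensor, w: Tensor, stride=1, pad=0) -> Tensor:
    """2-D convolution (cross-correlation), weights (O, C, KH, KW), no bias.

    Backward distributes the column gradient back with a KHxKW loop of
    strided adds, which keeps memory flat.
    """
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    if kh == 1 and kw == 1 and pad == 0:
        return _conv1x1(x, w, stride)
    sh = sw = stride
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    view, oh, ow = _patches(xp, kh, kw, sh, sw)
    cols = view.reshape(n * oh * ow, c * kh * kw)
    wmat = w.data.reshape(o, c * kh * kw)
    out_data = (cols @ wmat.T).reshape(n, oh, ow, o).transpose(0, 3, 1, 2)
    out = Tensor(out_data, _needs_grad(x, w), (x, w))

    def back(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
        if w.requires_grad:
            w.accumulate((gmat.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, oh, ow, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x.accumulate(dxp)

    out._backward = back
    return out


def maxpool2d(x: Tensor, k=3, stride=2, pad=1) -> Tensor:
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    view, oh, ow = _patches(xp, k, k, stride, stride)
    flat = view.reshape(n, oh, ow, c, k * k)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data.transpose(0, 3, 1, 2), x.requires_grad, (x,))

    def back(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=np.float32)
        gi = g.transpose(0, 2, 3, 1)  # (N, OH, OW, C)
        ki, kj = np.unravel_index(idx, (k, k))
        nn, oi, oj, cc = np.indices(idx.shape, sparse=False)
        np.add.at(dxp, (nn, cc, oi * stride + ki, oj * stride + kj), gi)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        x.accumulate(dxp)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# batch normalization with frozen affine (scale 1, shift 0)


class BatchNorm2d:
    """Per-channel standardization over (N, H, W).

    The affine parameters are permanently frozen at scale 1, shift 0, so
    the layer has no trainable state; it only tracks running statistics
    for evaluation mode.
    """

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        # frozen affine transform: these never change
        self.scale = 1.0
        self.shift = 0.0

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out = Tensor(xhat, x.requires_grad, (x,))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def back(g):
            if not x.requires_grad:
                return
            if training:
                gm = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gx = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                dx = inv[None, :, None, None] * (g - gm - xhat * gx)
            else:
                dx = g * inv[None, :, None, None]
            x.accumulate(dx.astype(np.float32))

        out._backward = back
        return out

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, st):
        self.running_mean = np.asarray(st["running_mean"], dtype=np.float32).copy()
        self.running_var = np.asarray(st["running_var"], dtype=np.float32).copy()


# ---------------------------------------------------------------------------
# loss


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch; labels are class indices."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    out = Tensor(nll, logits.requires_grad, (logits,))

    def back(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), labels] -= 1.0
            logits.accumulate(g * d / n)

    out._backward = back
    return out
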