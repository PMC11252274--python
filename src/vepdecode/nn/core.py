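"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
records the closure needed to push gradients to its parents.  Only the ops
required by the networks in this package are provided, but each is a proper
general-purpose implementation (broadcasting, batched matmul, grouped
convolution).  Heavy ops (convolution, pooling, batch normalisation,
cross-entropy) carry hand-written backward passes so that no large
intermediate graphs are materialised.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "matmul", "softmax", "cross_entropy_logits",
           "conv2d", "max_pool2d", "avg_pool2d", "batch_norm", "group_norm",
           "dropout", "upsample2x_nearest", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-free logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        # First write stores a reference (no copy); later writes allocate a
        # fresh sum so closures never mutate arrays they do not own.
        if self.grad is None:
            self.grad = g if g.dtype == self.data.dtype else g.astype(self.data.dtype)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        # iterative post-order DFS: a recursive closure here would form a
        # reference cycle keeping the whole graph (and its activations)
        # alive until the garbage collector runs
        topo, seen = [], {id(self)}
        stack = [(self, iter(self._parents))]
        while stack:
            node, it = stack[-1]
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    break
            else:
                topo.append(node)
                stack.pop()
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free interior gradients/graph as we go
                if t is not self:
                    t.grad = None
                t._backward = None
                t._parents = ()

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(
            np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        o = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.shape))
        return Tensor._make(self.data + o.data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)
        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.shape))
        return Tensor._make(self.data * o.data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.data, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g * self.data / o.data ** 2, o.shape))
        return Tensor._make(self.data / o.data, (self, o), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))
        return Tensor._make(self.data ** p, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)
        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)
        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)
        return Tensor._make(out_data, (self,), bwd)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))
        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))
        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- activations ----------------------------------------------------------
    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * np.expm1(np.minimum(x, 0.0))
        out_data = np.where(x > 0, x, neg)

        def bwd(g):
            self._accumulate(g * np.where(x > 0, 1.0, neg + alpha).astype(x.dtype))
        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)
        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        s = _stable_sigmoid(self.data)

        def bwd(g):
            self._accumulate(g * s * (1.0 - s))
        return Tensor._make(s, (self,), bwd)

    def silu(self):
        s = _stable_sigmoid(self.data)
        out_data = self.data * s

        def bwd(g):
            self._accumulate(g * (s + out_data * (1.0 - s)))
        return Tensor._make(out_data, (self,), bwd)

    def tanh(self):
        t = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - t * t))
        return Tensor._make(t, (self,), bwd)

    def __matmul__(self, other):
        return matmul(self, other)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"


# -- free functions -----------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""

    def bwd(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))
    return Tensor._make(np.matmul(a.data, b.data), (a, b), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))
    return Tensor._make(y, (x,), bwd)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between ``logits`` (B, K) and integer ``labels``."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1)) - z[np.arange(n), labels]
    loss = lse.mean()

    def bwd(g):
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate((g / n) * p.astype(logits.dtype))
    return Tensor._make(np.asarray(loss, dtype=logits.dtype), (logits,), bwd)


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None,
           stride=1, padding=(0, 0, 0, 0), groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation (NCHW).

    ``padding`` is ``(top, bottom, left, right)`` which permits the asymmetric
    'same' padding needed for even-length kernels.
    """
    sh, sw = _pair(stride)
    pt, pb, pl, pr = padding
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    G = groups
    assert Cin == Cin_g * G and Cout % G == 0
    Cout_g = Cout // G

    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr))) \
        if (pt or pb or pl or pr) else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    if kh == Hp and kw == 1 and sh == 1 and sw == 1:
        # full-height kernel (e.g. the spatial filter over all electrodes):
        # contract with einsum directly, skipping the im2col copy entirely.
        xg = xp.reshape(B, G, Cin_g * Hp, Wp)
        wg = w.data.reshape(G, Cout_g, Cin_g * kh)
        out = np.matmul(wg[None], xg).reshape(B, Cout, 1, Wp)
        if bias is not None:
            out += bias.data.reshape(1, Cout, 1, 1)

        def bwd_s(g):
            gg = g.reshape(B, G, Cout_g, Wp)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.matmul(gg, xg.swapaxes(-1, -2)).sum(axis=0)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gx = np.matmul(wg.swapaxes(-1, -2)[None], gg) \
                       .reshape(B, Cin, Hp, Wp)
                x._accumulate(gx[:, :, pt:Hp - pb, pl:Wp - pr])
        return Tensor._make(out, (x, w) if bias is None else (x, w, bias), bwd_s)

    parents = (x, w) if bias is None else (x, w, bias)

    if G == 1 and Cin_g == 1 and kh == 1 and sh == 1 and sw == 1:
        # wide 1-D kernel (temporal filter): build the (B, K, Ho, Wo) window
        # stack with K streaming slice copies and keep a (B, C, P) layout so
        # every GEMM and the col2im scatter run on contiguous rows — this
        # path is memory-bandwidth critical.
        P = Ho * Wo
        patchesT = np.empty((B, kw, Ho, Wo), dtype=x.dtype)
        xp2 = xp[:, 0]
        for k in range(kw):
            patchesT[:, k] = xp2[:, :, k:k + Wo]
        patchesT = patchesT.reshape(B, kw, P)
        wmat2 = w.data.reshape(Cout, kw)
        out = np.matmul(wmat2, patchesT).reshape(B, Cout, Ho, Wo)
        if bias is not None:
            out += bias.data.reshape(1, Cout, 1, 1)

        def bwd_t(g):
            gr3 = g.reshape(B, Cout, P)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.matmul(gr3, patchesT.swapaxes(1, 2)).sum(axis=0)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gp3 = np.matmul(wmat2.T, gr3).reshape(B, kw, Ho, Wo)
                gxp = np.zeros((B, 1, Hp, Wp), dtype=x.dtype)
                gx2 = gxp[:, 0]
                for k in range(kw):
                    gx2[:, :, k:k + Wo] += gp3[:, k]
                x._accumulate(gxp[:, :, pt:Hp - pb, pl:Wp - pr])
        return Tensor._make(out, parents, bwd_t)

    if G == Cin and Cin_g == 1 and Cout_g == 1 and kh == 1 and sh == sw == 1:
        # depthwise 1-D kernel: small K, vectorised shift-accumulate
        out = np.zeros((B, Cout, Ho, Wo), dtype=x.dtype)
        wd = w.data.reshape(Cout, kw)
        for k in range(kw):
            out += xp[:, :, :, k:k + Wo] * wd[None, :, None, k, None]
        if bias is not None:
            out += bias.data.reshape(1, Cout, 1, 1)

        def bwd_d(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.empty((Cout, kw), dtype=x.dtype)
                for k in range(kw):
                    gw[:, k] = np.einsum("bchw,bchw->c", g,
                                         xp[:, :, :, k:k + Wo], optimize=False)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                gxp = np.zeros((B, Cin, Hp, Wp), dtype=x.dtype)
                for k in range(kw):
                    gxp[:, :, :, k:k + Wo] += g * wd[None, :, None, k, None]
                x._accumulate(gxp[:, :, pt:Hp - pb, pl:Wp - pr])
        return Tensor._make(out, parents, bwd_d)

    # generic grouped path (im2col)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    if Cin_g == 1:
        patches = np.ascontiguousarray(win.reshape(B, G, Ho * Wo, kh * kw))
    else:
        patches = np.ascontiguousarray(
            win.reshape(B, G, Cin_g, Ho, Wo, kh * kw).transpose(0, 1, 3, 4, 2, 5)
        ).reshape(B, G, Ho * Wo, Cin_g * kh * kw)
    wmat = w.data.reshape(G, Cout_g, Cin_g * kh * kw)
    out = np.ascontiguousarray(
        np.matmul(wmat[None], patches.swapaxes(2, 3))
    ).reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out += bias.data.reshape(1, Cout, 1, 1)

    def bwd(g):
        gr = g.reshape(B, G, Cout_g, Ho * Wo)                # (B,G,Og,P)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(gr, patches).sum(axis=0)
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gp = np.matmul(gr.transpose(0, 1, 3, 2), wmat)   # (B,G,P,Cin_g*kh*kw)
            gp = gp.reshape(B, G, Ho, Wo, Cin_g, kh * kw)
            gxp = np.zeros((B, Cin, Hp, Wp), dtype=x.dtype)
            gxv = gxp.reshape(B, G, Cin_g, Hp, Wp)
            k = 0
            for i in range(kh):
                for j in range(kw):
                    gxv[:, :, :, i:i + Ho * sh:sh, j:j + Wo * sw:sw] += \
                        np.moveaxis(gp[..., k], 4, 2)
                    k += 1
            x._accumulate(gxp[:, :, pt:Hp - pb, pl:Wp - pr])
    return Tensor._make(out, parents, bwd)


def max_pool2d(x: Tensor, kernel) -> Tensor:
    """Non-overlapping max pool; trailing remainder along each axis is dropped."""
    kh, kw = _pair(kernel)
    B, C, H, W = x.shape
    Ho, Wo = H // kh, W // kw
    xc = x.data[:, :, :Ho * kh, :Wo * kw]
    xr = xc.reshape(B, C, Ho, kh, Wo, kw).transpose(0, 1, 2, 4, 3, 5) \
           .reshape(B, C, Ho, Wo, kh * kw)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros((B, C, Ho, Wo, kh * kw), dtype=x.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros((B, C, H, W), dtype=x.dtype)
        gx[:, :, :Ho * kh, :Wo * kw] = gr.reshape(B, C, Ho, Wo, kh, kw) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * kh, Wo * kw)
        x._accumulate(gx)
    return Tensor._make(out, (x,), bwd)


def avg_pool2d(x: Tensor, kernel) -> Tensor:
    kh, kw = _pair(kernel)
    B, C, H, W = x.shape
    Ho, Wo = H // kh, W // kw
    xc = x.data[:, :, :Ho * kh, :Wo * kw]
    out = xc.reshape(B, C, Ho, kh, Wo, kw).mean(axis=(3, 5))

    def bwd(g):
        gx = np.zeros((B, C, H, W), dtype=x.dtype)
        gx[:, :, :Ho * kh, :Wo * kw] = np.repeat(
            np.repeat(g, kh, axis=2), kw, axis=3) / (kh * kw)
        x._accumulate(gx)
    return Tensor._make(out, (x,), bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; updates running stats in place."""
    B, C, H, W = x.shape
    n = B * H * W
    x3 = x.data.reshape(B, C, H * W)
    if training:
        # contiguous-axis reductions; the squared sum is a fused einsum pass
        mu = x3.sum(axis=2).sum(axis=0) / n
        sq = np.einsum("bcs,bcs->c", x3, x3, optimize=False) / n
        var = np.maximum(sq - mu * mu, 0.0)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    mu = np.asarray(mu, dtype=x.dtype)
    ivar = (1.0 / np.sqrt(var + eps)).astype(x.dtype)
    xhat = x3 - mu[None, :, None]
    xhat *= ivar[None, :, None]
    out = xhat * gamma.data[None, :, None]
    out += beta.data[None, :, None]
    out = out.reshape(B, C, H, W)

    def bwd(g):
        g3 = g.reshape(B, C, H * W)
        gxsum = np.einsum("bcs,bcs->c", g3, xhat, optimize=False)
        gsum = g3.sum(axis=2).sum(axis=0)
        if gamma.requires_grad:
            gamma._accumulate(gxsum)
        if beta.requires_grad:
            beta._accumulate(gsum)
        if x.requires_grad:
            gi = (gamma.data * ivar)[None, :, None]
            if training:
                gx = xhat * (-gxsum / n)[None, :, None].astype(x.dtype)
                gx += g3
                gx -= (gsum / n)[None, :, None].astype(x.dtype)
                gx *= gi
            else:
                gx = gi * g3
            x._accumulate(gx.reshape(B, C, H, W))
    return Tensor._make(out, (x, gamma, beta), bwd)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               groups: int, eps: float = 1e-5) -> Tensor:
    B, C, H, W = x.shape
    G = groups
    xg = x.data.reshape(B, G, C // G * H * W)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * ivar).reshape(B, C, H, W).astype(x.dtype)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            n = C // G * H * W
            gx = (g * gamma.data.reshape(1, C, 1, 1)).reshape(B, G, n)
            xh = xhat.reshape(B, G, n)
            gsum = gx.sum(axis=2, keepdims=True)
            gxsum = (gx * xh).sum(axis=2, keepdims=True)
            gi = ivar * (gx - gsum / n - xh * gxsum / n)
            x._accumulate(gi.reshape(B, C, H, W).astype(x.dtype))
    return Tensor._make(out.astype(x.dtype), (x, gamma, beta), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape, dtype=np.float32) >= p).astype(x.dtype) / (1.0 - p)

    def bwd(g):
        x._accumulate(g * keep)
    return Tensor._make(x.data * keep, (x,), bwd)


def upsample2x_nearest(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        gx = g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
        x._accumulate(gx)
    return Tensor._make(out, (x,), bwd)
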