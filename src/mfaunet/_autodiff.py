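"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the primitives the vessel
segmentation network needs: broadcasting arithmetic, (grouped) 2-D
convolution via im2col, batched matrix products for attention, softmax,
pooling reductions and separable bilinear resizing.  Forward values are
a configurable float type (float64 by default); gradients are accumulated into ``Tensor.grad``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import special as _sp


DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the working float type (float32 roughly halves training time)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate ``grad`` (default: ones) from this tensor."""
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts):
    return any(t.requires_grad for t in ts)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data + b.data, _needs(a, b), (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    out._backward = bwd
    return out


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data * b.data, _needs(a, b), (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = bwd
    return out


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data / b.data, _needs(a, b), (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    out._backward = bwd
    return out


def _unary(a, value, dval):
    a = astensor(a)
    out = Tensor(value, a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * dval)

    out._backward = bwd
    return out


def relu(a) -> Tensor:
    a = astensor(a)
    return _unary(a, np.maximum(a.data, 0.0), (a.data > 0).astype(DTYPE))


def sigmoid(a) -> Tensor:
    a = astensor(a)
    s = _sp.expit(a.data)
    return _unary(a, s, s * (1.0 - s))


def gelu(a) -> Tensor:
    a = astensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))
    pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return _unary(a, x * cdf, cdf + x * pdf)


def log(a) -> Tensor:
    a = astensor(a)
    return _unary(a, np.log(a.data), 1.0 / a.data)


def sqrt(a) -> Tensor:
    a = astensor(a)
    r = np.sqrt(a.data)
    return _unary(a, r, 0.5 / r)


def square(a) -> Tensor:
    a = astensor(a)
    return _unary(a, a.data ** 2, 2.0 * a.data)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where no clamping occurred."""
    a = astensor(a)
    inside = ((a.data > lo) & (a.data < hi)).astype(DTYPE)
    return _unary(a, np.clip(a.data, lo, hi), inside)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), a.requires_grad, (a,))

    def bwd(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).astype(DTYPE))
            return
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(axes):
                gg = np.expand_dims(gg, ax)
        a._accum(np.broadcast_to(gg, a.shape).astype(DTYPE))

    out._backward = bwd
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(a, axis, keepdims=False) -> Tensor:
    """Maximum over ``axis``; ties share the gradient equally."""
    a = astensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == m).astype(DTYPE)
    mask = mask / mask.sum(axis=axis, keepdims=True)
    val = m if keepdims else np.squeeze(m, axis=axis)
    out = Tensor(val, a.requires_grad, (a,))

    def bwd(g):
        if not a.requires_grad:
            return
        gg = g if keepdims else np.expand_dims(g, axis)
        a._accum(mask * gg)

    out._backward = bwd
    return out


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out = Tensor(a.data.reshape(shape), a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g.reshape(a.shape))

    out._backward = bwd
    return out


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    inv = np.argsort(axes)
    out = Tensor(a.data.transpose(axes), a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    out._backward = bwd
    return out


def concat(tensors, axis=1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _needs(*tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Batched matrix product over the last two axes (numpy semantics)."""
    a, b = astensor(a), astensor(b)
    out = Tensor(np.matmul(a.data, b.data), _needs(a, b), (a, b))

    def bwd(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.shape))

    out._backward = bwd
    return out


def softmax(a, axis=-1) -> Tensor:
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

    out._backward = bwd
    return out


def batchnorm2d(x, gamma, beta, eps: float = 1e-5):
    """Fused training-mode batch normalisation over (N, H, W) per channel.

    Returns ``(out, batch_mean, batch_var)``; the statistics are plain
    arrays for running-average bookkeeping.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    axes = (0, 2, 3)
    m = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - m) * inv
    gsh = gamma.data.reshape(1, -1, 1, 1)
    out = Tensor(xhat * gsh + beta.data.reshape(1, -1, 1, 1),
                 _needs(x, gamma, beta), (x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gh = g * gsh
            t1 = gh.mean(axis=axes, keepdims=True)
            t2 = (gh * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv * (gh - t1 - xhat * t2))

    out._backward = bwd
    return out, m.ravel(), var.ravel()


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pad_hw(x, ph, pw):
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _conv1x1(x, w, b, stride):
    """Fast path: pointwise convolution as a channel-mixing matmul."""
    n, cin, hin, win = x.shape
    cout = w.shape[0]
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    oh, ow = xs.shape[2], xs.shape[3]
    wmat = w.data.reshape(cout, cin)
    y = np.matmul(wmat, xs.reshape(n, cin, oh * ow)).reshape(n, cout, oh, ow)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _needs(*parents), parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gmat = g.reshape(n, cout, oh * ow)
        if w.requires_grad:
            gw = np.einsum("nop,ncp->oc", gmat, xs.reshape(n, cin, oh * ow),
                           optimize=True)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gxs = np.matmul(wmat.T, gmat).reshape(n, cin, oh, ow)
            if stride > 1:
                gx = np.zeros_like(x.data)
                gx[:, :, ::stride, ::stride] = gxs
            else:
                gx = gxs
            x._accum(gx)

    out._backward = bwd
    return out


def _conv_fft(x, w, b, padding):
    """Large-kernel stride-1 'same' cross-correlation in the Fourier domain."""
    from scipy import fft as sfft

    n, cin, hin, win = x.shape
    cout, _, kh, kw = w.shape
    p = padding
    lh = sfft.next_fast_len(hin + kh - 1)
    lw = sfft.next_fast_len(win + kw - 1)
    fx = sfft.rfft2(x.data, s=(lh, lw))                  # (N, C, LH, LWr)
    fw = sfft.rfft2(w.data[:, :, ::-1, ::-1], s=(lh, lw))
    fy = np.einsum("ncuv,ocuv->nouv", fx, fw, optimize=True)
    yfull = sfft.irfft2(fy, s=(lh, lw))
    r0, c0 = kh - 1 - p, kw - 1 - p
    y = np.ascontiguousarray(yfull[:, :, r0:r0 + hin, c0:c0 + win]).astype(
        DTYPE, copy=False)
    if b is not None:
        y += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _needs(*parents), parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        fg = sfft.rfft2(g, s=(lh, lw))
        if w.requires_grad:
            # lag correlation of input with the output gradient
            fwgrad = np.einsum("nouv,ncuv->ocuv", np.conj(fg), fx,
                               optimize=True)
            corr = sfft.irfft2(fwgrad, s=(lh, lw))
            rows = (np.arange(kh) - p) % lh
            cols = (np.arange(kw) - p) % lw
            w._accum(corr[:, :, rows[:, None], cols[None, :]].astype(
                DTYPE, copy=False))
        if x.requires_grad:
            fw2 = sfft.rfft2(w.data, s=(lh, lw))
            fxg = np.einsum("nouv,ocuv->ncuv", fg, fw2, optimize=True)
            xfull = sfft.irfft2(fxg, s=(lh, lw))
            x._accum(np.ascontiguousarray(
                xfull[:, :, p:p + hin, p:p + win]).astype(DTYPE, copy=False))

    out._backward = bwd
    return out


def conv2d(x, w, b=None, stride=1, padding=0, groups=1) -> Tensor:
    """2-D cross-correlation, NCHW layout, same semantics as torch.conv2d."""
    x, w = astensor(x), astensor(w)
    if b is not None:
        b = astensor(b)
    sh = sw = int(stride)
    ph = pw = int(padding)
    n, cin, hin, win = x.shape
    cout, cin_g, kh, kw = w.shape
    if cin_g * groups != cin or cout % groups:
        raise ValueError("channel/group mismatch in conv2d")
    if kh == 1 and kw == 1 and groups == 1 and ph == 0 and pw == 0:
        return _conv1x1(x, w, b, sh)
    if (groups == 1 and sh == 1 and kh == kw and kh >= 7
            and 2 * ph == kh - 1):
        return _conv_fft(x, w, b, ph)
    xp = _pad_hw(x.data, ph, pw)
    oh = (xp.shape[2] - kh) // sh + 1
    ow = (xp.shape[3] - kw) // sw + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::sh, ::sw]                      # (N, C, OH, OW, KH, KW)

    if groups == cin and cin_g == 1 and cout == cin:
        # depthwise: contract only over the kernel window
        y = np.einsum("ncyxkl,ckl->ncyx", view, w.data[:, 0], optimize=True)
        if b is not None:
            y = y + b.data.reshape(1, cout, 1, 1)
        parents = (x, w) if b is None else (x, w, b)
        out = Tensor(y, _needs(*parents), parents)

        def bwd_dw(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.einsum("ncyx,ncyxkl->ckl", g, view, optimize=True)
                w._accum(gw[:, None])
            if x.requires_grad:
                gx = np.zeros_like(xp)
                wd = w.data
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += (
                            g * wd[None, :, 0, i, j, None, None])
                if ph or pw:
                    gx = gx[:, :, ph:gx.shape[2] - ph, pw:gx.shape[3] - pw]
                x._accum(gx)

        out._backward = bwd_dw
        return out

    if groups == 1:
        # im2col + BLAS for the forward/weight passes; per-offset matmuls
        # (no six-dimensional transposes) for the input gradient
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * oh * ow, cin * kh * kw)
        wmat = w.data.reshape(cout, cin * kh * kw)
        y = np.ascontiguousarray(
            (cols @ wmat.T).reshape(n, oh, ow, cout).transpose(0, 3, 1, 2))
        if b is not None:
            y += b.data.reshape(1, cout, 1, 1)
        parents = (x, w) if b is None else (x, w, b)
        out = Tensor(y, _needs(*parents), parents)

        def bwd_g1(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gmat = np.ascontiguousarray(
                    g.transpose(0, 2, 3, 1)).reshape(n * oh * ow, cout)
                w._accum((gmat.T @ cols).reshape(w.shape))
            if x.requires_grad:
                gflat = np.ascontiguousarray(g).reshape(n, cout, oh * ow)
                gx = np.zeros_like(xp)
                wd = w.data
                for i in range(kh):
                    for j in range(kw):
                        gs = np.matmul(wd[:, :, i, j].T, gflat)
                        gx[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += (
                            gs.reshape(n, cin, oh, ow))
                if ph or pw:
                    gx = gx[:, :, ph:gx.shape[2] - ph, pw:gx.shape[3] - pw]
                x._accum(gx)

        out._backward = bwd_g1
        return out
    # general grouped convolution
    og = cout // groups
    vg = view.reshape(n, groups, cin_g, oh, ow, kh, kw)
    wg = w.data.reshape(groups, og, cin_g, kh, kw)
    y = np.einsum("ngcyxkl,gockl->ngoyx", vg, wg, optimize=True).reshape(
        n, cout, oh, ow)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _needs(*parents), parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gg = g.reshape(n, groups, og, oh, ow)
        if w.requires_grad:
            gw = np.einsum("ngoyx,ngcyxkl->gockl", gg, vg,
                           optimize=True).reshape(cout, cin_g, kh, kw)
            w._accum(gw)
        if x.requires_grad:
            wg2 = w.data.reshape(groups, og, cin_g, kh, kw)
            gcol = np.einsum("ngoyx,gockl->ngcklyx", gg, wg2,
                             optimize=True).reshape(n, cin, kh, kw, oh, ow)
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += gcol[:, :, i, j]
            if ph or pw:
                gx = gx[:, :, ph:gx.shape[2] - ph, pw:gx.shape[3] - pw]
            x._accum(gx)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# resizing (separable linear interpolation, pixel-centre convention)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        f = int(np.floor(src))
        t = src - f
        if f + 1 <= n_in - 1:
            m[i, f] += 1.0 - t
            m[i, f + 1] += t
        else:
            m[i, f] += 1.0
    return m


def resize2d(x, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor (align_corners=False convention)."""
    x = astensor(x)
    n, c, h, w = x.shape
    mh = _resize_matrix(h, out_h).astype(DTYPE)
    mw = _resize_matrix(w, out_w).astype(DTYPE)
    y = np.einsum("oh,nchw->ncow", mh, x.data, optimize=True)
    y = np.einsum("pw,ncow->ncop", mw, y, optimize=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.einsum("oh,ncow->nchw", mh, np.einsum(
                "pw,ncop->ncow", mw, g, optimize=True), optimize=True)
            x._accum(gx)

    out._backward = bwd
    return out
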