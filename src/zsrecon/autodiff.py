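"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based engine supporting the operations the unrolled
reconstruction model needs: complex arithmetic, centered unitary FFTs,
2-D convolution on real channel stacks, leaky ReLU, and the reductions
used by the k-space losses.

Conventions
-----------
Every differentiated scalar objective is real.  For a complex tensor ``z``
the stored gradient is the *pair gradient* ``dL/dRe(z) + i dL/dIm(z)``, so
a gradient-descent step is simply ``z -= lr * z.grad``.  For a real tensor
the gradient is the ordinary partial derivative.  With this convention the
backward rule of any C-linear operator ``A`` is its Hermitian adjoint
``A^H``, and elementwise product ``a*b`` back-propagates ``g*conj(b)``.

All functional ops accept either :class:`Tensor` or plain ``numpy``
arrays/scalars; with no Tensor argument (or inside :func:`no_grad`) they
fall through to numpy, so the same code path serves training, inference
and plain numerical use.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor", "no_grad", "add", "sub", "neg", "mul", "div", "conj",
    "absolute", "log1p", "exp", "sqrt", "square", "sum_all", "vdot_real",
    "fft2c", "ifft2c", "stack", "unstack", "complex_to_channels",
    "channels_to_complex", "conv2d", "leaky_relu", "asarray",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording within the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus (optionally) a node in the backward tape."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return neg(self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    # -- backward pass ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative topological sort (graphs can be thousands of nodes deep)
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                order.append(node)
                stack_.pop()

        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go; keep leaf gradients
                node._backward = None
                node._parents = ()


def asarray(x):
    """Underlying numpy array of a Tensor, or ``np.asarray`` of anything else."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _tracked(*args) -> bool:
    return _GRAD_ENABLED and any(
        isinstance(a, Tensor) and a.requires_grad for a in args
    )


def _accumulate(t: Tensor, g: np.ndarray):
    if not isinstance(t, Tensor) or not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, copy=True)
    else:
        t.grad = t.grad + g


def _make(data, parents, backward):
    out = Tensor(data, requires_grad=True)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor) and p.requires_grad)
    out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = g.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _to_grad_for(t, g):
    """Cast gradient to real if the variable is real-valued."""
    td = asarray(t)
    if not np.iscomplexobj(td) and np.iscomplexobj(g):
        return g.real
    return g


# ----------------------------------------------------------------------
# elementwise arithmetic
# ----------------------------------------------------------------------

def add(a, b):
    ad_, bd = asarray(a), asarray(b)
    data = ad_ + bd
    if not _tracked(a, b):
        return Tensor(data) if isinstance(a, Tensor) or isinstance(b, Tensor) else data

    def backward(g):
        _accumulate(a, _to_grad_for(a, _unbroadcast(g, ad_.shape)))
        _accumulate(b, _to_grad_for(b, _unbroadcast(g, bd.shape)))

    return _make(data, (a, b), backward)


def sub(a, b):
    return add(a, neg(b))


def neg(a):
    ad_ = asarray(a)
    data = -ad_
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, -g)

    return _make(data, (a,), backward)


def mul(a, b):
    ad_, bd = asarray(a), asarray(b)
    data = ad_ * bd
    if not _tracked(a, b):
        return Tensor(data) if isinstance(a, Tensor) or isinstance(b, Tensor) else data

    def backward(g):
        _accumulate(a, _to_grad_for(a, _unbroadcast(g * np.conj(bd), ad_.shape)))
        _accumulate(b, _to_grad_for(b, _unbroadcast(g * np.conj(ad_), bd.shape)))

    return _make(data, (a, b), backward)


def div(a, b):
    """Elementwise division; ``b`` must be real-valued."""
    ad_, bd = asarray(a), asarray(b)
    if np.iscomplexobj(bd):
        raise TypeError("div supports real denominators only")
    data = ad_ / bd
    if not _tracked(a, b):
        return Tensor(data) if isinstance(a, Tensor) or isinstance(b, Tensor) else data

    def backward(g):
        _accumulate(a, _to_grad_for(a, _unbroadcast(g / bd, ad_.shape)))
        _accumulate(b, _to_grad_for(b, _unbroadcast(-(g * np.conj(data)).real / bd, bd.shape)))

    return _make(data, (a, b), backward)


def conj(a):
    ad_ = asarray(a)
    data = np.conj(ad_)
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, np.conj(g))

    return _make(data, (a,), backward)


def absolute(a):
    """Complex (or real) magnitude; real-valued output."""
    ad_ = asarray(a)
    data = np.abs(ad_)
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        safe = np.where(data == 0, 1.0, data)
        _accumulate(a, _to_grad_for(a, g * ad_ / safe))

    return _make(data, (a,), backward)


def _real_unary(a, fn, dfn):
    ad_ = asarray(a)
    if np.iscomplexobj(ad_):
        raise TypeError("real-valued input required")
    data = fn(ad_)
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, g * dfn(ad_, data))

    return _make(data, (a,), backward)


def log1p(a):
    return _real_unary(a, np.log1p, lambda x, y: 1.0 / (1.0 + x))


def exp(a):
    return _real_unary(a, np.exp, lambda x, y: y)


def sqrt(a):
    return _real_unary(a, np.sqrt, lambda x, y: 0.5 / np.where(y == 0, 1.0, y))


def square(a):
    return _real_unary(a, np.square, lambda x, y: 2.0 * x)


def leaky_relu(a, slope: float = 0.1):
    ad_ = asarray(a)
    if np.iscomplexobj(ad_):
        raise TypeError("leaky_relu acts on real channel stacks")
    data = np.where(ad_ >= 0, ad_, slope * ad_)
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, g * np.where(ad_ >= 0, 1.0, slope))

    return _make(data, (a,), backward)


# ----------------------------------------------------------------------
# reductions
# ----------------------------------------------------------------------

def sum_all(a):
    """Sum of all entries of a real tensor (0-d output)."""
    ad_ = asarray(a)
    if np.iscomplexobj(ad_):
        raise TypeError("sum_all is for real tensors; use vdot_real for complex")
    data = ad_.sum()
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, np.broadcast_to(g, ad_.shape).astype(ad_.dtype, copy=False))

    return _make(data, (a,), backward)


def vdot_real(a, b):
    """Re <a, b> = Re(sum(conj(a) * b)); real 0-d output."""
    ad_, bd = asarray(a), asarray(b)
    data = np.real(np.vdot(ad_.ravel(), bd.ravel()))
    if not _tracked(a, b):
        return Tensor(data) if isinstance(a, Tensor) or isinstance(b, Tensor) else data

    def backward(g):
        _accumulate(a, _to_grad_for(a, g * bd))
        _accumulate(b, _to_grad_for(b, g * ad_))

    return _make(data, (a, b), backward)


# ----------------------------------------------------------------------
# Fourier transforms (centered, unitary, last two axes)
# ----------------------------------------------------------------------

_AX = (-2, -1)


def _fft2c_data(x):
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AX), axes=_AX, norm="ortho"), axes=_AX
    )


def _ifft2c_data(x):
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_AX), axes=_AX, norm="ortho"), axes=_AX
    )


def fft2c(a):
    ad_ = asarray(a)
    data = _fft2c_data(ad_)
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, _to_grad_for(a, _ifft2c_data(g)))

    return _make(data, (a,), backward)


def ifft2c(a):
    ad_ = asarray(a)
    data = _ifft2c_data(ad_)
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, _to_grad_for(a, _fft2c_data(g)))

    return _make(data, (a,), backward)


# ----------------------------------------------------------------------
# structural ops
# ----------------------------------------------------------------------

def stack(parts):
    """Stack tensors along a new leading axis."""
    datas = [asarray(p) for p in parts]
    data = np.stack(datas, axis=0)
    if not _tracked(*parts):
        return Tensor(data) if any(isinstance(p, Tensor) for p in parts) else data

    def backward(g):
        for i, p in enumerate(parts):
            _accumulate(p, _to_grad_for(p, g[i]))

    return _make(data, tuple(parts), backward)


def unstack(a, index: int):
    """Select one slice along the leading axis."""
    ad_ = asarray(a)
    data = ad_[index]
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        full = np.zeros_like(ad_)
        full[index] = g
        _accumulate(a, full)

    return _make(data, (a,), backward)


def complex_to_channels(a):
    """(K, H, W) complex -> (2K, H, W) real: [Re_1..Re_K, Im_1..Im_K]."""
    ad_ = asarray(a)
    data = np.concatenate([ad_.real, ad_.imag], axis=0)
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    k = ad_.shape[0]

    def backward(g):
        _accumulate(a, g[:k] + 1j * g[k:])

    return _make(data, (a,), backward)


def channels_to_complex(a):
    """(2K, H, W) real -> (K, H, W) complex, inverse of complex_to_channels."""
    ad_ = asarray(a)
    k = ad_.shape[0] // 2
    if ad_.shape[0] != 2 * k:
        raise ValueError("even channel count required")
    data = ad_[:k] + 1j * ad_[k:]
    if not _tracked(a):
        return Tensor(data) if isinstance(a, Tensor) else data

    def backward(g):
        _accumulate(a, np.concatenate([g.real, g.imag], axis=0))

    return _make(data, (a,), backward)


# ----------------------------------------------------------------------
# 2-D convolution on real channel stacks
# ----------------------------------------------------------------------

def _conv2d_data(x, w, b):
    """x: (Cin,H,W), w: (Cout,Cin,kh,kw), b: (Cout,); same zero padding."""
    cin, H, W = x.shape
    cout, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (Cin, H, W, kh, kw)
    out = np.einsum("chwij,ocij->ohw", win, w, optimize=True)
    return out + b[:, None, None]


def conv2d(x, w, b):
    """Same-padded 2-D convolution (cross-correlation) on a channel stack."""
    xd, wd, bd = asarray(x), asarray(w), asarray(b)
    if np.iscomplexobj(xd):
        raise TypeError("conv2d acts on real channel stacks")
    data = _conv2d_data(xd, wd, bd)
    if not _tracked(x, w, b):
        return Tensor(data) if any(isinstance(t, Tensor) for t in (x, w, b)) else data

    cout, cin, kh, kw = wd.shape
    ph, pw = kh // 2, kw // 2

    def backward(g):
        # grad wrt bias
        _accumulate(b, g.sum(axis=(1, 2)))
        # grad wrt weights: correlate padded input with grad_out
        xp = np.pad(xd, ((0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(xp, g.shape[1:], axis=(1, 2))
        # win: (Cin, kh, kw, H, W)
        gw = np.einsum("cijhw,ohw->ocij", win, g, optimize=True)
        _accumulate(w, gw)
        # grad wrt input: full correlation of grad_out with flipped kernels
        gp = np.pad(g, ((0, 0), (ph, ph), (pw, pw)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(1, 2))
        wflip = wd[:, :, ::-1, ::-1]
        gx = np.einsum("ohwij,ocij->chw", gwin, wflip, optimize=True)
        _accumulate(x, gx)

    return _make(data, (x, w, b), backward)
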