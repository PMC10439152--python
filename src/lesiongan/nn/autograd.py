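"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tape: every operation returns a new :class:`Tensor`
whose ``_backward`` closure scatters the incoming gradient into its parents.
Only the operations the segmentation networks need are provided — elementwise
arithmetic, reductions, activations, slicing/concatenation, 2-D convolution
(strided, dilated, depthwise), and bilinear resampling.  All data is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concat",
    "conv2d",
    "bilinear_resize",
    "global_avg_pool",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph plumbing -----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float32), self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() only supported for scalar tensors")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g / b.data)
                if b.requires_grad:
                    b._accum(-g * a.data / (b.data * b.data))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out.requires_grad:
            def bw(g, a=self, e=exponent):
                a._accum(g * e * (a.data ** (e - 1.0)))
            out._backward = bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bw(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, tuple(ax % len(shape) for ax in axes))
                a._accum(np.broadcast_to(g, shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shaping -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def bw(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                full[idx] = g
                a._accum(full)
            out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = _make(out_data, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, o=out_data: a._accum(g * o)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * np.sign(a.data))
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = _make(s, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, s=s: a._accum(g * s * (1.0 - s))
        return out

    def swish(self):
        """x * sigmoid(x) (SiLU)."""
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = _make(self.data * s, (self,))
        if out.requires_grad:
            def bw(g, a=self, s=s):
                a._accum(g * (s + a.data * s * (1.0 - s)))
            out._backward = bw
        return out

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * (a.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = _make(np.where(self.data > 0, self.data, slope * self.data), (self,))
        if out.requires_grad:
            def bw(g, a=self, slope=slope):
                a._accum(g * np.where(a.data > 0, 1.0, slope))
            out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True`` by construction)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = np.asarray(data, dtype=np.float32)
    out.grad = None
    out.requires_grad = any(p.requires_grad for p in parents)
    out._prev = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
    out._backward = None
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]

        def bw(g, ts=tensors, sizes=sizes, axis=axis):
            offset = 0
            for t, n in zip(ts, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + n)
                if t.requires_grad:
                    t._accum(g[tuple(sl)])
                offset += n
        out._backward = bw
    return out


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0,
           dilation=1, groups: int = 1) -> Tensor:
    """2-D cross-correlation on NCHW input.

    ``w`` has shape (C_out, C_in/groups, kH, kW).  Only ``groups == 1`` and
    depthwise (``groups == C_in`` with C_out == C_in) are supported, which is
    all the inverted-bottleneck architectures need.  Implemented as a sum of
    shifted pointwise products so dilated and depthwise cases stay cheap.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    depthwise = groups != 1
    if depthwise and not (groups == C and Cout == C and Cin_g == 1):
        raise ValueError("only groups=1 or full depthwise convolution supported")
    if not depthwise and Cin_g != C:
        raise ValueError(f"weight expects {Cin_g} input channels, got {C}")

    Ho = (H + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    Wo = (W + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"convolution output would be empty for input {H}x{W}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data

    out = np.zeros((B, Cout, Ho, Wo), dtype=np.float32)
    slices = []
    for dy in range(kh):
        for dx in range(kw):
            ys = slice(dy * dh, dy * dh + sh * (Ho - 1) + 1, sh)
            xs_ = slice(dx * dw, dx * dw + sw * (Wo - 1) + 1, sw)
            patch = xp[:, :, ys, xs_]
            slices.append((dy, dx, ys, xs_))
            if depthwise:
                out += patch * w.data[:, 0, dy, dx][None, :, None, None]
            else:
                out += np.matmul(
                    w.data[:, :, dy, dx], patch.reshape(B, C, Ho * Wo)
                ).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    res = _make(out, parents)
    if res.requires_grad:
        def bw(g):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            need_x = x.requires_grad
            need_w = w.requires_grad
            gxp = np.zeros_like(xp) if need_x else None
            gw = np.zeros_like(w.data) if need_w else None
            g2 = g.reshape(B, Cout, Ho * Wo)
            for dy, dx, ys, xs_ in slices:
                patch = xp[:, :, ys, xs_]
                if depthwise:
                    if need_w:
                        gw[:, 0, dy, dx] = np.einsum("bchw,bchw->c", g, patch)
                    if need_x:
                        gxp[:, :, ys, xs_] += g * w.data[:, 0, dy, dx][None, :, None, None]
                else:
                    if need_w:
                        gw[:, :, dy, dx] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                    if need_x:
                        gxp[:, :, ys, xs_] += np.matmul(
                            w.data[:, :, dy, dx].T, g2
                        ).reshape(B, C, Ho, Wo)
            if need_w:
                w._accum(gw)
            if need_x:
                gx = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
                x._accum(gx)
        res._backward = bw
    return res


_interp_cache: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Half-pixel-centered bilinear interpolation matrix (n_out x n_in)."""
    key = (n_out, n_in)
    m = _interp_cache.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=np.float32)
        src = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = (src - i0).astype(np.float32)
        m[np.arange(n_out), i0] += 1.0 - frac
        m[np.arange(n_out), i1] += frac
        _interp_cache[key] = m
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Resize NCHW tensor spatially with bilinear interpolation."""
    x = as_tensor(x)
    H, W = x.data.shape[-2:]
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return x
    Mh = _interp_matrix(Ho, H)
    Mw = _interp_matrix(Wo, W)
    out = _make(np.matmul(np.matmul(Mh, x.data), Mw.T), (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, Mh=Mh, Mw=Mw: a._accum(
            np.matmul(np.matmul(Mh.T, g), Mw)
        )
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over spatial dims of NCHW, keeping them as 1x1."""
    return x.mean(axis=(2, 3), keepdims=True)
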