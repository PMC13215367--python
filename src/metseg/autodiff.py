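"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a numpy array and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation over the recorded
graph.  The op set is deliberately small — exactly what a 3D
encoder/transformer/decoder segmentation network and its losses need:
broadcasting arithmetic, matmul (batched), reductions, exp/log/pow, shape
ops, a fused :func:`conv3d` primitive, nearest-neighbour upsampling and an
argmax-routed ``max`` reduction.

Tensors preserve their input dtype (float32 or float64): the network runs in
float32 for speed, while the losses accept float64 inputs so that
finite-difference gradient checks retain full precision.  Python scalars are
coerced to the partner tensor's dtype and never promote a float32 graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concatenate", "conv3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
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

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the subgraph that requires grad
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def leaky_relu(self, alpha: float = 0.01):
        """max(x, alpha*x); the small negative slope keeps gradients alive
        in units that a large optimisation step has driven negative."""
        slope = np.where(self.data > 0, 1.0, alpha).astype(self.data.dtype)
        out = Tensor(self.data * slope, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * slope)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient flows only where unclamped."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy()
                            if np.ndim(g) else np.full(self.shape, g))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient routes to the first arg-max (ties
        broken deterministically)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = Tensor(out_data, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full)
        out._backward = bw
        return out

    def logsumexp(self, axis: int, keepdims: bool = False):
        """Numerically stable log-sum-exp (shift-invariant, exact gradient)."""
        shift = np.max(self.data, axis=axis, keepdims=True)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        shifted = self - Tensor(shift)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
        if not keepdims:
            out = out.reshape(tuple(np.delete(out.shape, axis)))
        return out

    def softmax(self, axis: int):
        shift = np.max(self.data, axis=axis, keepdims=True)
        e = (self - Tensor(shift)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)
        out._backward = bw
        return out

    def upsample3d(self, factor: int = 2):
        """Nearest-neighbour upsampling of the three trailing axes."""
        d = self.data
        for ax in (-3, -2, -1):
            d = np.repeat(d, factor, axis=ax)
        out = Tensor(d, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            B, C, D, H, W = self.shape
            f = factor
            g = g.reshape(B, C, D, f, H, f, W, f).sum(axis=(3, 5, 7))
            self._accum(g)
        out._backward = bw
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def conv3d(x: Tensor, w: Tensor, b: Tensor,
           stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution (cross-correlation) as a single autodiff primitive.

    ``x``: (B, C, D, H, W); ``w``: (O, C, k, k, k); ``b``: (O,).  Uses an
    im2col layout built from k^3 strided slice copies (cache-friendly) and a
    batched matmul; the backward pass is the matching col2im fold.
    """
    x, w, b = astensor(x), astensor(w), astensor(b)
    B, C, D, H, W = x.shape
    O, _, k, _, _ = w.shape
    xp = np.pad(x.data, [(0, 0), (0, 0)] + [(padding, padding)] * 3) \
        if padding else x.data
    s = stride
    Do = (D + 2 * padding - k) // s + 1
    Ho = (H + 2 * padding - k) // s + 1
    Wo = (W + 2 * padding - k) // s + 1
    L = Do * Ho * Wo
    cols = np.empty((B, C, k ** 3, L), dtype=xp.dtype)
    i = 0
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                sub = xp[:, :, kd:kd + s * Do:s, kh:kh + s * Ho:s,
                         kw:kw + s * Wo:s]
                cols[:, :, i] = sub.reshape(B, C, L)
                i += 1
    cols = cols.reshape(B, C * k ** 3, L)
    wmat = w.data.reshape(O, C * k ** 3)
    out_data = (wmat @ cols).reshape(B, O, Do, Ho, Wo) \
        + b.data.reshape(1, O, 1, 1, 1)
    out = Tensor(out_data, parents=(x, w, b))

    def bw(g):
        gmat = g.reshape(B, O, L)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)            # B, C*k^3, L
            gcols = gcols.reshape(B, C, k ** 3, Do, Ho, Wo)
            gxp = np.zeros_like(xp)
            i = 0
            for kd in range(k):
                for kh in range(k):
                    for kw in range(k):
                        gxp[:, :, kd:kd + s * Do:s, kh:kh + s * Ho:s,
                            kw:kw + s * Wo:s] += gcols[:, :, i]
                        i += 1
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding,
                          padding:-padding]
            x._accum(gxp)
    out._backward = bw
    return out


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out
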