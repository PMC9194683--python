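"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the metapath attention model needs:
elementwise arithmetic and activations, matrix products, row gathers,
segment reductions (for per-target attention softmax over variable-size
instance groups), concatenation and complex-pair interleaving for the
rotation encoder.

A :class:`Tensor` wraps an ``ndarray`` plus an optional gradient buffer.
Graphs are built eagerly; calling :meth:`Tensor.backward` on a scalar
output runs a topological sweep and accumulates ``.grad`` on every
tensor created with ``requires_grad=True``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "interleave",
    "segment_sum",
    "segment_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data: np.ndarray | float | Sequence,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        name: str | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents = _parents
        self.name = name

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(x: "Tensor | float | np.ndarray") -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        needs = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs, _parents=parents if needs else ())
        if needs:
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other: float) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other: "Tensor | float") -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions & shaping ------------------------------------------
    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(ge, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.data.shape

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Select rows ``self[idx]``; gradient scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accumulate(buf)

        return self._make(self.data[idx], (self,), backward)

    # -- nonlinearities -------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # stable two-branch form avoids overflow for large |x|
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * np.where(pos, 1.0, out_data + alpha))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        pos = self.data > 0

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * np.where(pos, 1.0, slope))

        return self._make(np.where(pos, self.data, slope * self.data), (self,), backward)

    def cos(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g * np.sin(self.data))

        return self._make(np.cos(self.data), (self,), backward)

    def sin(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * np.cos(self.data))

        return self._make(np.sin(self.data), (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        inside = (self.data > lo) & (self.data < hi)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- backward sweep -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- free functions on tensors ----------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    needs = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=needs, _parents=tuple(tensors) if needs else ())
    if needs:
        out._backward = backward
    return out


def interleave(re: Tensor, im: Tensor) -> Tensor:
    """Merge real/imaginary halves into even/odd columns of a (N, d) tensor."""
    if re.shape != im.shape:
        raise ValueError("real and imaginary parts must have matching shapes")
    n, h = re.shape
    data = np.empty((n, 2 * h))
    data[:, 0::2] = re.data
    data[:, 1::2] = im.data

    def backward(g: np.ndarray) -> None:
        if re.requires_grad:
            re._accumulate(g[:, 0::2])
        if im.requires_grad:
            im._accumulate(g[:, 1::2])

    needs = re.requires_grad or im.requires_grad
    out = Tensor(data, requires_grad=needs, _parents=(re, im) if needs else ())
    if needs:
        out._backward = backward
    return out


def even_cols(t: Tensor) -> Tensor:
    idx = np.arange(0, t.shape[-1], 2)
    return gather_cols(t, idx)


def odd_cols(t: Tensor) -> Tensor:
    idx = np.arange(1, t.shape[-1], 2)
    return gather_cols(t, idx)


def gather_cols(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g: np.ndarray) -> None:
        if t.requires_grad:
            buf = np.zeros_like(t.data)
            np.add.at(buf.T, idx, g.T)
            t._accumulate(buf)

    return t._make(t.data[..., idx], (t,), backward)


def segment_sum(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise sum of ``t`` into ``num_segments`` groups.

    Uses ``np.add.reduceat`` when segments are sorted (the model keeps
    them sorted), falling back to ``np.add.at`` otherwise.
    """
    segments = np.asarray(segments, dtype=np.intp)
    data = np.zeros((num_segments,) + t.data.shape[1:])
    if len(segments) and np.all(segments[1:] >= segments[:-1]):
        present, starts = np.unique(segments, return_index=True)
        data[present] = np.add.reduceat(t.data, starts, axis=0)
    else:
        np.add.at(data, segments, t.data)

    def backward(g: np.ndarray) -> None:
        if t.requires_grad:
            t._accumulate(g[segments])

    return t._make(data, (t,), backward)


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``scores`` (N,) or (N, K) within each segment.

    Numerically stabilised by subtracting the detached per-segment max;
    the shift cancels in the gradient so detaching is exact.
    """
    segments = np.asarray(segments, dtype=np.intp)
    shifted_max = np.full((num_segments,) + scores.data.shape[1:], -np.inf)
    if len(segments) and np.all(segments[1:] >= segments[:-1]):
        present, starts = np.unique(segments, return_index=True)
        shifted_max[present] = np.maximum.reduceat(scores.data, starts, axis=0)
    else:
        np.maximum.at(shifted_max, segments, scores.data)
    shifted = scores - Tensor(shifted_max[segments])
    ex = shifted.exp()
    denom = segment_sum(ex, segments, num_segments)
    return ex / denom.gather_rows(segments)


def attention_pool(alpha: Tensor, enc: Tensor, segments: np.ndarray,
                   num_segments: int) -> Tensor:
    """Fused multi-head attention pooling.

    ``alpha`` (N, K) are attention coefficients, ``enc`` (N, d) instance
    encodings, both grouped by sorted ``segments``. Returns the (num_segments,
    K*d) head-major concatenation of the per-segment weighted sums
    ``sum_n alpha[n, k] * enc[n]``.
    """
    segments = np.asarray(segments, dtype=np.intp)
    n, k = alpha.data.shape
    d = enc.data.shape[1]
    data = np.zeros((num_segments, k * d))
    sorted_segs = len(segments) == 0 or np.all(segments[1:] >= segments[:-1])
    if sorted_segs and len(segments):
        present, starts = np.unique(segments, return_index=True)
        for j in range(k):
            data[present, j * d:(j + 1) * d] = np.add.reduceat(
                alpha.data[:, j, None] * enc.data, starts, axis=0)
    else:
        for j in range(k):
            np.add.at(data[:, j * d:(j + 1) * d], segments,
                      alpha.data[:, j, None] * enc.data)

    def backward(g: np.ndarray) -> None:
        ga = np.empty_like(alpha.data) if alpha.requires_grad else None
        ge = np.zeros_like(enc.data) if enc.requires_grad else None
        for j in range(k):
            gj = g[segments, j * d:(j + 1) * d]
            if ga is not None:
                ga[:, j] = (gj * enc.data).sum(axis=1)
            if ge is not None:
                ge += gj * alpha.data[:, j, None]
        if ga is not None:
            alpha._accumulate(ga)
        if ge is not None:
            enc._accumulate(ge)

    return alpha._make(data, (alpha, enc), backward)


def rotate_complex(x: Tensor, theta: Tensor, sign: float = 1.0) -> Tensor:
    """Rotate complex coordinate pairs of ``x`` (N, d) by phases
    ``sign * theta`` (d/2,). Even columns are real parts, odd imaginary."""
    if x.data.shape[-1] % 2 != 0:
        raise ValueError("last dimension must be even")
    z = np.ascontiguousarray(x.data).view(np.complex128)
    rot = np.exp(1j * sign * theta.data)
    w = z * rot

    def backward(g: np.ndarray) -> None:
        gz = np.ascontiguousarray(g).view(np.complex128)
        if x.requires_grad:
            gx = (gz * np.conj(rot)).view(np.float64)
            x._accumulate(gx)
        if theta.requires_grad:
            # d(w)/d(theta_j) = i * sign * w_j
            gt = sign * (gz.imag * w.real - gz.real * w.imag).sum(axis=0)
            theta._accumulate(gt)

    return x._make(w.view(np.float64), (x, theta), backward)


def parameter(rng: np.random.Generator, shape: tuple[int, ...],
              scale: float | None = None, name: str | None = None) -> Tensor:
    """Glorot-style initialised learnable tensor."""
    if scale is None:
        fan = sum(shape) if len(shape) > 1 else shape[0]
        scale = float(np.sqrt(2.0 / max(fan, 1)))
    t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True, name=name)
    return t


class Adam:
    """Adam optimiser with decoupled-style L2 weight decay added to the gradient."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
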