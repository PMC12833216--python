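"""A compact reverse-mode automatic differentiation engine over numpy.

Every model in this package is small (the largest baseline has ~156k scalar
parameters), so a tape-based engine with vectorised numpy kernels is both
sufficient and dependency-free. The design follows the classic pattern:
a :class:`Tensor` wraps an ndarray, records its parents and a closure that
accumulates gradients, and ``backward()`` walks the tape in reverse
topological order.

Besides the usual arithmetic/NN primitives, two domain-specific primitives
are provided with hand-derived Jacobians:

* :func:`exp_rotvec` — the so(3) -> SO(3) exponential (Rodrigues), smooth
  through the identity via Taylor-expanded coefficients;
* :func:`log_rotmat` — the SO(3) -> so(3) logarithm on its smooth branch
  (angle bounded away from pi, which holds for body-segment orientations
  during gait).

Both are finite-difference-verified in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "transpose",
    "reshape",
    "stack",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "sqrt",
    "absolute",
    "atan2",
    "asin",
    "wrap_deg",
    "softmax",
    "mean_all",
    "huber_mean",
    "exp_rotvec",
    "log_rotmat",
    "Adam",
]

_SMALL = 1e-4


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS (graphs can be deep for long compositions)
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        return self + (-other)

    def __rsub__(self, other):
        return constant(other) + (-self)

    def __mul__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data * other.data))

        out._backward = bw
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def item(self) -> float:
        return float(self.data)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=float))


def parameter(x, name: str = "") -> Tensor:
    return Tensor(np.asarray(x, dtype=float), requires_grad=True, name=name)


# -- structural ops -------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a = a if isinstance(a, Tensor) else constant(a)
    b = b if isinstance(b, Tensor) else constant(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else np.outer(g, b.data)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g if a.data.ndim > 1 else np.outer(a.data, g)
            b._accum(_unbroadcast(gb, b.data.shape))

    out._backward = bw
    return out


def transpose(x: Tensor, axes=None) -> Tensor:
    """General axis permutation; default swaps the last two axes."""
    if axes is None:
        axes = tuple(range(x.data.ndim - 2)) + (x.data.ndim - 1, x.data.ndim - 2)
    inv = np.argsort(axes)
    out = Tensor(np.transpose(x.data, axes), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(np.transpose(g, inv))
    return out


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape
    out = Tensor(x.data.reshape(shape), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g.reshape(orig))
    return out


def stack(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else constant(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(np.squeeze(piece, axis=axis))

    out._backward = bw
    return out


# -- elementwise nonlinearities -------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * s * (1 - s))
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * (1 - t * t))
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * e)
    return out


def sqrt(x: Tensor) -> Tensor:
    s = np.sqrt(x.data)
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * 0.5 / np.maximum(s, 1e-300))
    return out


def absolute(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * np.sign(x.data))
    return out


def atan2(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise two-argument arctangent atan2(a, b)."""
    out = Tensor(np.arctan2(a.data, b.data), parents=(a, b))

    def bw(g):
        denom = a.data * a.data + b.data * b.data
        if a.requires_grad:
            a._accum(g * b.data / denom)
        if b.requires_grad:
            b._accum(-g * a.data / denom)

    out._backward = bw
    return out


def asin(x: Tensor) -> Tensor:
    """arcsin with input clipped to [-1, 1]; gradient clipped near the poles."""
    xd = np.clip(x.data, -1.0, 1.0)
    out = Tensor(np.arcsin(xd), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(
        g / np.sqrt(np.maximum(1.0 - xd * xd, 1e-12))
    )
    return out


def wrap_deg(x: Tensor) -> Tensor:
    """Wrap angular values (degrees) to (-180, 180]; gradient is identity a.e."""
    r = np.mod(x.data, 360.0)
    r = np.where(r > 180.0, r - 360.0, r)
    out = Tensor(r, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    out._backward = bw
    return out


def mean_all(x: Tensor) -> Tensor:
    return x.sum() / float(x.data.size)


def huber_mean(diff: Tensor, delta: float = 1.0) -> Tensor:
    """Mean Huber penalty of ``diff`` (quadratic below delta, linear above)."""
    d = diff.data
    absd = np.abs(d)
    vals = np.where(absd <= delta, 0.5 * d * d, delta * (absd - 0.5 * delta))
    out = Tensor(vals.mean(), parents=(diff,))
    out._backward = lambda g: diff.requires_grad and diff._accum(
        g * np.clip(d, -delta, delta) / d.size
    )
    return out


# -- SO(3) primitives ------------------------------------------------------

def _ab_coeffs(theta):
    small = theta < _SMALL
    t = np.where(small, 1.0, theta)
    t2 = theta * theta
    a = np.where(small, 1.0 - t2 / 6.0 + t2 * t2 / 120.0, np.sin(t) / t)
    b = np.where(small, 0.5 - t2 / 24.0 + t2 * t2 / 720.0, (1.0 - np.cos(t)) / (t * t))
    # alpha = a'(t)/t, beta = b'(t)/t  (both smooth at 0)
    alpha = np.where(
        small, -1.0 / 3.0 + t2 / 30.0, (t * np.cos(t) - np.sin(t)) / (t ** 3)
    )
    beta = np.where(
        small,
        -1.0 / 12.0 + t2 / 180.0,
        (t * np.sin(t) - 2.0 * (1.0 - np.cos(t))) / (t ** 4),
    )
    return a, b, alpha, beta


def _hat_np(v):
    K = np.zeros(v.shape[:-1] + (3, 3))
    K[..., 0, 1] = -v[..., 2]
    K[..., 0, 2] = v[..., 1]
    K[..., 1, 0] = v[..., 2]
    K[..., 1, 2] = -v[..., 0]
    K[..., 2, 0] = -v[..., 1]
    K[..., 2, 1] = v[..., 0]
    return K


def _skew_dot(G):
    """<G, hat(e_i)> for i = 0,1,2 — the antisymmetric contraction."""
    return np.stack(
        [
            G[..., 2, 1] - G[..., 1, 2],
            G[..., 0, 2] - G[..., 2, 0],
            G[..., 1, 0] - G[..., 0, 1],
        ],
        axis=-1,
    )


def exp_rotvec(v: Tensor) -> Tensor:
    """Differentiable Rodrigues map: rotation vector (..., 3) -> (..., 3, 3)."""
    vd = v.data
    theta = np.linalg.norm(vd, axis=-1)
    a, b, alpha, beta = _ab_coeffs(theta)
    K = _hat_np(vd)
    K2 = K @ K
    R = np.eye(3) + a[..., None, None] * K + b[..., None, None] * K2

    def bw(G):
        if not v.requires_grad:
            return
        # dR/dv_i = (alpha v_i) K + a E_i + (beta v_i) K^2 + b (E_i K + K E_i)
        gK = np.einsum("...mn,...mn->...", G, K)
        gK2 = np.einsum("...mn,...mn->...", G, K2)
        term1 = (alpha * gK + beta * gK2)[..., None] * vd
        term2 = a[..., None] * _skew_dot(G)
        # <G, E_i K + K E_i> = -skew_dot(G K + K G)  (using K^T = -K)
        mix = -_skew_dot(G @ K + K @ G)
        term3 = b[..., None] * mix
        v._accum(term1 + term2 + term3)

    out = Tensor(R, parents=(v,), backward=bw)
    return out


def log_rotmat(R: Tensor) -> Tensor:
    """Differentiable SO(3) logarithm on the smooth branch (theta < pi).

    Inputs with angle within ~1e-3 of pi are clamped; gait-segment
    orientations never approach that branch in practice.
    """
    Rd = R.data
    tr = Rd[..., 0, 0] + Rd[..., 1, 1] + Rd[..., 2, 2]
    c = np.clip((tr - 1.0) / 2.0, -1.0 + 1e-6, 1.0)
    theta = np.arccos(c)
    w = _skew_dot(Rd)  # (R - R^T) contracted = 2 sin(theta) * axis
    small = theta < _SMALL
    safe_sin = np.where(small, 1.0, np.sin(theta))
    gamma = np.where(small, 0.5 + theta * theta / 12.0, theta / (2.0 * safe_sin))
    vd = gamma[..., None] * w
    # d gamma / d c, smooth at theta = 0 (limit -1/6)
    dgamma_dc = np.where(
        small,
        -1.0 / 6.0 - theta * theta / 30.0,
        (theta * c - np.sin(theta)) / (2.0 * safe_sin ** 3),
    )

    def bw(g):
        if not R.requires_grad:
            return
        G = np.zeros_like(Rd)
        gg = gamma[..., None] * g
        G[..., 2, 1] += gg[..., 0]
        G[..., 1, 2] -= gg[..., 0]
        G[..., 0, 2] += gg[..., 1]
        G[..., 2, 0] -= gg[..., 1]
        G[..., 1, 0] += gg[..., 2]
        G[..., 0, 1] -= gg[..., 2]
        gw = np.einsum("...i,...i->...", g, w)
        diag = 0.5 * dgamma_dc * gw
        G[..., 0, 0] += diag
        G[..., 1, 1] += diag
        G[..., 2, 2] += diag
        R._accum(G)

    return Tensor(vd, parents=(R,), backward=bw)


# -- optimiser -------------------------------------------------------------

class Adam:
    """Adam with optional (coupled) L2 weight decay, as in the classic form."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
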