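"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the contrastive training stack needs:
broadcasting arithmetic, matmul, stride-1 same-padded 1D convolution,
ReLU, reductions, exp/log/pow and element selection.  Gradients are
accumulated on every node that requires them, so intermediate activations
(e.g. the last convolution feature maps used by Grad-CAM) can be queried
after ``backward``.

Float64 throughout: the package favours exact reproducibility and
finite-difference-checkable gradients over raw speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "batchnorm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._backward = _backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit recursion limits
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
        self._accum(np.broadcast_to(grad, self.data.shape))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(self.data ** e, _parents=(self,))
        out._backward = lambda g: self._accum(g * e * self.data ** (e - 1.0))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0.0))
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        ax = axes or None
        out = Tensor(self.data.transpose(ax), _parents=(self,))
        inv = np.argsort(ax) if ax else None
        out._backward = lambda g: self._accum(g.transpose(inv) if inv is not None else g.T)
        return out

    def take_rows(self, index: np.ndarray):
        """Row selection ``x[index]`` with scatter-add backward."""
        index = np.asarray(index)
        out = Tensor(self.data[index], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accum(full)

        out._backward = bw
        return out

    # ------------------------------------------------------------ convolution
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Stride-1, length-preserving ("same") 1D convolution.

        self: (N, C, L); weight: (F, C, K); bias: (F,).  Even kernels pad one
        extra position on the left so the output length is exactly L.
        """
        x, w = self.data, weight.data
        n, c, length = x.shape
        f, c2, k = w.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
        pl, pr = (k - 1) // 2 + (1 - k % 2), (k - 1) // 2
        xp = np.zeros((n, c, length + pl + pr))
        xp[:, :, pl : pl + length] = x
        # K shifted batched matmuls: y += W[:,:,j] @ xp[:,:,j:j+L]
        y = np.zeros((n, f, length))
        for j in range(k):
            y += np.matmul(w[None, :, :, j], xp[:, :, j : j + length])
        if bias is not None:
            y += bias.data[None, :, None]
        out = Tensor(y, _parents=(self, weight) + ((bias,) if bias is not None else ()))

        def bw(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if weight.requires_grad:
                dw = np.empty_like(w)
                for j in range(k):
                    dw[:, :, j] = np.tensordot(g, xp[:, :, j : j + length],
                                               axes=([0, 2], [0, 2]))
                weight._accum(dw)
            if self.requires_grad:
                dxp = np.zeros_like(xp)
                for j in range(k):
                    dxp[:, :, j : j + length] += np.matmul(w[None, :, :, j].transpose(0, 2, 1), g)
                self._accum(dxp[:, :, pl : pl + length])

        out._backward = bw
        return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
              eps: float = 1e-5,
              stats: tuple[np.ndarray, np.ndarray] | None = None
              ) -> tuple[Tensor, tuple[np.ndarray, np.ndarray]]:
    """Fused batch normalization (single graph node, analytic backward).

    Normalizes over ``axes``; gamma/beta broadcast along the kept axes.
    With ``stats`` given (running mean/var, eval mode) those are treated
    as constants; otherwise batch statistics are used and differentiated
    through.
    """
    xd = x.data
    shape = tuple(1 if i in axes else s for i, s in enumerate(xd.shape))
    if stats is not None:
        mu, var = (s.reshape(shape) for s in stats)
        use_batch = False
    else:
        mu = xd.mean(axis=axes, keepdims=True)
        var = xd.var(axis=axes, keepdims=True)
        use_batch = True
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * invstd
    g_b, b_b = gamma.data.reshape(shape), beta.data.reshape(shape)
    out = Tensor(xhat * g_b + b_b, _parents=(x, gamma, beta))
    count = int(np.prod([xd.shape[a] for a in axes]))  # elements per channel

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes).reshape(beta.data.shape))
        if x.requires_grad:
            dxhat = g * g_b
            if use_batch:
                dx = (invstd / count) * (
                    count * dxhat
                    - dxhat.sum(axis=axes, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
            else:
                dx = dxhat * invstd
            x._accum(dx)

    out._backward = bw
    return out, (mu.reshape(-1), var.reshape(-1))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out
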