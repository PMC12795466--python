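"""Reverse-mode automatic differentiation over numpy arrays.

The training stack (graph-transformer encoders, adversarial discriminator,
Adam) runs full-batch on matrices of a few hundred rows, so a small
tape-based engine over dense float64 numpy arrays is sufficient and keeps
the numerical behaviour fully transparent. Gradients flow through matmul,
broadcast arithmetic, the usual pointwise nonlinearities, reductions,
shape ops, row gathers, and a gradient-reversal node.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the Tensor's reflected operators
    # instead of numpy broadcasting over the Tensor as an object scalar
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._result(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            return (g * e * self.data ** (e - 1.0),)

        return Tensor._result(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            ga = g @ other.data.swapaxes(-1, -2)
            gb = self.data.swapaxes(-1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._result(self.data @ other.data, (self, other), backward)

    # -- pointwise -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._result(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._result(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed only through the interior."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            return (g * mask,)

        return Tensor._result(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._result(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._result(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = tuple(np.argsort(axes))

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._result(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            return (g.swapaxes(a, b),)

        return Tensor._result(self.data.swapaxes(a, b), (self,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def take_rows(self, idx):
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            out = np.zeros(self.shape, dtype=np.float64)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._result(self.data[idx], (self,), backward)

    # -- domain-adaptation specific ---------------------------------------
    def gradient_reversal(self, lam: float):
        """Identity forward; backward multiplies the gradient by -lam."""
        lam = float(lam)

        def backward(g):
            return (-lam * g,)

        return Tensor._result(self.data.copy(), (self,), backward)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros(parent.shape, dtype=np.float64)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


class Adam:
    """Adam with optional L2 weight decay, over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros(p.shape) for p in self.params]
        self._v = [np.zeros(p.shape) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
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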