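"""Minimal reverse-mode automatic differentiation with the layers the
annotation network needs.

The engine is deliberately small: float32 tensors, a handful of ops
(matmul, broadcast arithmetic, relu/sigmoid/exp/log, reductions, row
gather/concat) and a gradient-reversal op. Every op's backward pass is
verified against central finite differences in the test suite, so the
composite network gradients can be trusted without a large framework.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (forward-only passes)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        if _grad_enabled:
            self._parents = parents
            self._backward = backward
            self.requires_grad = requires_grad or any(
                p.requires_grad for p in parents
            )
        else:
            self._parents = ()
            self._backward = None
            self.requires_grad = False

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (a scalar unless `grad` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the subgraph that requires grad
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                pgrad = pgrad.astype(DTYPE, copy=False)
                if parent.grad is None:
                    parent.grad = pgrad.copy() if pgrad.base is not None else pgrad
                else:
                    parent.grad = parent.grad + pgrad

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self.data / other.data
        return Tensor(
            out,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * out / other.data, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = self.data**exponent
        return Tensor(
            out,
            parents=(self,),
            backward=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            backward=lambda g: (g @ other.data.T, self.data.T @ g),
        )

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(
            self.data * mask, parents=(self,), backward=lambda g: (g * mask,)
        )

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(
            out, parents=(self,), backward=lambda g: (g * out * (1.0 - out),)
        )

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * out,))

    def log(self) -> "Tensor":
        return Tensor(
            np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,)
        )

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * 0.5 / out,))

    def clamp_min(self, lo: float) -> "Tensor":
        mask = self.data >= lo
        return Tensor(
            np.maximum(self.data, lo), parents=(self,), backward=lambda g: (g * mask,)
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape),)

        return Tensor(out, parents=(self,), backward=backward)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structural ops -------------------------------------------------------
    def take_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.data[idx], parents=(self,), backward=backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along the cell (row) axis."""
    sizes = [t.shape[0] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def backward(g):
        return tuple(g[offsets[i]: offsets[i + 1]] for i in range(len(tensors)))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=0),
        parents=tuple(tensors),
        backward=backward,
    )


def grad_reverse(t: Tensor, lam: float) -> Tensor:
    """Gradient reversal: identity forward, gradient scaled by -lam backward.

    Inserting this between the encoder and the domain discriminator turns the
    discriminator's minimisation into the encoder's maximisation, which is how
    the adversarial alignment of source and target feature distributions is
    trained with a single optimizer.
    """
    if lam < 0:
        raise ValueError("gradient reversal coefficient must be >= 0")
    return Tensor(t.data, parents=(t,), backward=lambda g: (-lam * g,))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # trainable even if built under no_grad


class Linear:
    """Affine layer with the uniform +-1/sqrt(fan_in) initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / math.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(n_out,)))

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def state(self) -> list[np.ndarray]:
        return [self.weight.data, self.bias.data]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        self.weight.data = arrays[0].astype(DTYPE)
        self.bias.data = arrays[1].astype(DTYPE)


class BatchNorm1d:
    """Batch normalisation over the cell axis with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(
        self, x: Tensor, train: bool = True, update_stats: bool = True
    ) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            if update_stats:
                n = x.shape[0]
                unbiased = var.data[0] * (n / max(n - 1, 1))
                m = self.momentum
                self.running_mean = (
                    (1 - m) * self.running_mean + m * mu.data[0]
                ).astype(DTYPE)
                self.running_var = (
                    (1 - m) * self.running_var + m * unbiased
                ).astype(DTYPE)
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def state(self) -> list[np.ndarray]:
        return [self.gamma.data, self.beta.data, self.running_mean, self.running_var]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        self.gamma.data = arrays[0].astype(DTYPE)
        self.beta.data = arrays[1].astype(DTYPE)
        self.running_mean = arrays[2].astype(DTYPE)
        self.running_var = arrays[3].astype(DTYPE)


class MLP:
    """Stack of Linear (+ optional BatchNorm) + activation blocks.

    `final_activation` controls whether the last Linear is followed by the
    block nonlinearity (used in the encoder) or left bare (decoder output,
    classifier logits, discriminator logit).
    """

    def __init__(
        self,
        dims: Sequence[int],
        rng: np.random.Generator,
        batchnorm: bool = True,
        final_activation: bool = False,
    ):
        self.layers: list[tuple[Linear, BatchNorm1d | None, bool]] = []
        n_blocks = len(dims) - 1
        for i in range(n_blocks):
            last = i == n_blocks - 1
            act = (not last) or final_activation
            bn = BatchNorm1d(dims[i + 1]) if (batchnorm and act) else None
            self.layers.append((Linear(dims[i], dims[i + 1], rng), bn, act))

    def __call__(
        self, x: Tensor, train: bool = True, update_stats: bool = True
    ) -> Tensor:
        for linear, bn, act in self.layers:
            x = linear(x)
            if bn is not None:
                x = bn(x, train=train, update_stats=update_stats)
            if act:
                x = x.relu()
        return x

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for linear, bn, _ in self.layers:
            params.extend(linear.parameters())
            if bn is not None:
                params.extend(bn.parameters())
        return params

    def state(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for linear, bn, _ in self.layers:
            arrays.extend(linear.state())
            if bn is not None:
                arrays.extend(bn.state())
        return arrays

    def load_state(self, arrays: Iterable[np.ndarray]) -> None:
        it = iter(arrays)
        for linear, bn, _ in self.layers:
            linear.load_state([next(it), next(it)])
            if bn is not None:
                bn.load_state([next(it), next(it), next(it), next(it)])


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


def clip_grad_norm(params: Sequence["Parameter"], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most max_norm.

    Returns the pre-clip norm. Parameters without gradients are ignored.
    """
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm > 0:
        scale = DTYPE(max_norm / norm)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class SGD:
    """SGD with momentum and decoupled-from-nothing L2 weight decay.

    Parameters whose gradient is None after a backward pass are skipped
    entirely (no weight decay, no momentum update). This is what makes
    ablation switches leave unused sub-networks bit-identical.
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        momentum: float = 0.9,
        weight_decay: float = 5e-4,
    ):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buffers: dict[int, np.ndarray] = {}

    def step(self, lr: float) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf = self._buffers.get(id(p))
            if buf is None:
                buf = np.zeros_like(p.data)
                self._buffers[id(p)] = buf
            buf *= self.momentum
            buf += g
            p.data = p.data - DTYPE(lr) * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# Functional helpers
# ---------------------------------------------------------------------------


def softmax(logits: Tensor) -> Tensor:
    """Row-wise softmax, shift-stabilised (the shift is treated as constant)."""
    shift = logits.data.max(axis=1, keepdims=True)
    e = (logits - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


def log_softmax(logits: Tensor) -> Tensor:
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - shift
    return z - z.exp().sum(axis=1, keepdims=True).log()
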