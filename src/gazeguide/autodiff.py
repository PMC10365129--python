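"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small convolutional networks on CPU and, during
training, differentiates losses defined on *rule-masked gradient maps*
(guided back-propagation / deconvNet saliency).  Because the ReLU masks
are treated as constants of the current forward pass, the masked backward
sweep is a chain of linear operations in the weights and can be written
as an ordinary *forward* computation in this graph — first-order
reverse-mode is then sufficient to obtain weight gradients of a loss on
the saliency map.

The engine computes in float64 by default (``compute_dtype`` switches
to float32 for training speed).  The op set is intentionally small:
dense and convolutional linear algebra (convolution and its input
adjoint are mutual primitives), elementwise arithmetic, ReLU / sigmoid
/ softplus, reductions, reshaping and concatenation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "compute_dtype",
    "get_dtype",
    "concat",
    "conv2d",
    "conv2d_input_adjoint",
    "upsample_nearest2x",
    "relu",
    "sigmoid",
    "softplus",
]

_DTYPE = np.float64


def get_dtype():
    return _DTYPE


class compute_dtype:
    """Context manager switching the engine's working precision.

    float64 is the default (exact-gradient tests rely on it); training
    switches to float32 for roughly a 3x CPU speedup.  Tensors created
    inside the context are cast on construction.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype).type

    def __enter__(self):
        global _DTYPE
        self._saved = _DTYPE
        _DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global _DTYPE
        _DTYPE = self._saved
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor._from_op(
            self.data ** p,
            (self,),
            lambda g: (g * p * self.data ** (p - 1.0),),
        )
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape)
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape)
            return ga, gb

        return Tensor._from_op(a @ b, (self, other), backward)

    # -- shaping --------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep accumulating ``.grad`` on requires_grad leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# -- nonlinearities -----------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0  # strict: d/dx ReLU at 0 taken as 0
    return Tensor._from_op(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -700, 700)))
    return Tensor._from_op(s, (x,), lambda g: (g * s * (1.0 - s),))


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), stable for |x| up to at least 1e4."""
    z = x.data
    out = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    return Tensor._from_op(out, (x,), lambda g: (g * s,))


# -- structural ops -----------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def _conv_geometry(h: int, w: int, k: int, stride: int, pad: int) -> tuple[int, int]:
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    return oh, ow


# -- convolution kernels ------------------------------------------------------
# One batched GEMM per pass over an explicit column buffer (im2col with
# cin-major tap layout, matching w.reshape(c_out, c_in*k*k)).


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """x: (N,C,H,W) -> cols: (N, C*k*k, oh*ow), contiguous."""
    n, c, h, w = x.shape
    oh, ow = _conv_geometry(h, w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k * k, oh * ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride]
            cols[:, :, i * k + j, :] = patch.reshape(n, c, oh * ow)
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(
    cols: np.ndarray, img_shape: tuple[int, ...], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add columns back onto the image."""
    n, c, h, w = img_shape
    oh, ow = _conv_geometry(h, w, k, stride, pad)
    cols4 = cols.reshape(n, c, k * k, oh * ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                cols4[:, :, i * k + j, :].reshape(n, c, oh, ow)
            )
    return xp[:, :, pad : pad + h, pad : pad + w] if pad else xp


def _conv_fwd_data(x, w, stride, pad, cols=None):
    """x: (N,Cin,H,W), w: (Cout,Cin,k,k) -> (N,Cout,oh,ow)."""
    n, _, h, wd = x.shape
    c_out, c_in, k, _ = w.shape
    oh, ow = _conv_geometry(h, wd, k, stride, pad)
    if cols is None:
        cols = _im2col(x, k, stride, pad)
    wm = np.ascontiguousarray(w.reshape(c_out, c_in * k * k))
    return np.matmul(wm, cols).reshape(n, c_out, oh, ow)


def _conv_dx_data(g, w, in_shape, stride, pad):
    """Adjoint of `_conv_fwd_data` in x; g: (N,Cout,oh,ow) -> (N,Cin,H,W)."""
    n, c_out = g.shape[:2]
    c_in, k = w.shape[1], w.shape[-1]
    wm = np.ascontiguousarray(w.reshape(c_out, c_in * k * k))
    gcols = np.matmul(wm.T.copy(), g.reshape(n, c_out, -1))
    return _col2im(gcols, in_shape, k, stride, pad)


def _conv_dw_data(x, g, k, stride, pad, cols=None):
    """Adjoint in w; x: (N,Cin,H,W), g: (N,Cout,oh,ow) -> (Cout,Cin,k,k)."""
    n, c_in = x.shape[:2]
    c_out = g.shape[1]
    if cols is None:
        cols = _im2col(x, k, stride, pad)
    gw = np.matmul(g.reshape(n, c_out, -1), cols.transpose(0, 2, 1)).sum(axis=0)
    return gw.reshape(c_out, c_in, k, k)


def conv2d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) as a differentiable primitive."""
    k = w.shape[-1]
    in_shape = x.shape
    cols = _im2col(x.data, k, stride, pad)  # reused by both adjoints

    def backward(g):
        return (
            _conv_dx_data(g, w.data, in_shape, stride, pad),
            _conv_dw_data(x.data, g, k, stride, pad, cols=cols),
        )

    return Tensor._from_op(
        _conv_fwd_data(x.data, w.data, stride, pad, cols=cols), (x, w), backward
    )


def conv2d_input_adjoint(
    s: Tensor, w: Tensor, in_shape: tuple[int, ...], stride: int = 1, pad: int = 0
) -> Tensor:
    """Transposed convolution: the adjoint of ``conv2d`` in its input.

    Used by the saliency sweep, where it must stay differentiable in
    both the sweep signal ``s`` and the weights ``w``:
    <g, conv_T(s, w)> = <conv(g, w), s> gives the two backward rules.
    """
    k = w.shape[-1]

    def backward(g):
        return (
            _conv_fwd_data(g, w.data, stride, pad),
            _conv_dw_data(g, s.data, k, stride, pad),
        )

    return Tensor._from_op(
        _conv_dx_data(s.data, w.data, in_shape, stride, pad), (s, w), backward
    )


def upsample_nearest2x(x: Tensor) -> Tensor:
    def backward(g):
        n, c, h2, w2 = g.shape
        return (g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)),)

    return Tensor._from_op(
        np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,), backward
    )
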