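"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the graph-attention network needs: broadcast
arithmetic, dense and sparse matrix products, elementwise nonlinearities,
axis reductions, reshape/concat, 1-D convolution, and a numerically stable
binary cross-entropy on logits.  Gradients are accumulated by reverse
topological traversal of the recorded operation tape.

Gather/scatter over graph edges and per-graph reductions are index-plan
operations (``gather_rows``/``segment_sum``/``weighted_neighbor_sum``) whose
adjoints are contiguous segment sums; a sparse-constant product ``spmm`` is
also provided.  Operations preserve the operand dtype, so a graph built on
float32 arrays runs single-precision end to end.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = [
    "Tensor",
    "tensor",
    "spmm",
    "gather_rows",
    "segment_sum",
    "scatter_matrix",
    "graph_norm",
    "conv1d",
    "concat",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward
        self._grad_owned = False

    # ---- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False

    def _accumulate(self, grad: np.ndarray):
        # first gradient is adopted without copying; only a second
        # contribution materialises an owned buffer
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, like=self)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, like=self))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, like=self)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, like=self)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # ---- elementwise -----------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.data
        )
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * 0.5 / y
        )
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * y * (1.0 - y)
        )
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype, copy=False)
        out = Tensor(self.data * factor, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * factor)
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg = alpha * np.expm1(np.minimum(self.data, 0.0))
        y = np.where(pos, self.data, neg)
        dy = np.where(pos, 1.0, neg + alpha)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * dy)
        return out

    # ---- shape & reduction ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(old)
        )
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                shape = tuple(
                    1 if i in axes else s for i, s in enumerate(self.shape)
                )
                g = g.reshape(shape)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a % self.data.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)


def _as_tensor(x, like: "Tensor | None" = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if like is not None and np.isscalar(x):
        # keep python scalars in the operand's dtype so float32 graphs
        # are not silently promoted to float64
        return Tensor(np.asarray(x, dtype=like.data.dtype))
    return Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=requires_grad)


def spmm(sp_matrix: sparse.spmatrix, x: Tensor) -> Tensor:
    """Sparse-constant times dense-variable product: ``S @ x``."""
    sp_csr = sparse.csr_matrix(sp_matrix)
    out = Tensor(sp_csr @ x.data, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(sp_csr.T @ g)

    out._backward = bw
    return out


def scatter_matrix(idx: np.ndarray, n_rows: int, dtype=np.float64) -> sparse.csr_matrix:
    """CSR operator summing entry ``k`` into row ``idx[k]`` (adjoint of a gather)."""
    e = len(idx)
    return sparse.csr_matrix(
        (np.ones(e, dtype=dtype), (idx, np.arange(e))), shape=(n_rows, e)
    )


def gather_rows(x: Tensor, idx: np.ndarray, scatter: sparse.csr_matrix) -> Tensor:
    """Row gather ``x[idx]`` whose adjoint is the given scatter-add operator."""
    out = Tensor(x.data[idx], parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(scatter @ g)

    out._backward = bw
    return out


def segment_sum(x: Tensor, scatter: sparse.csr_matrix, seg_ids: np.ndarray) -> Tensor:
    """Scatter-sum rows of ``x`` into ``scatter``'s rows; adjoint is a gather."""
    out = Tensor(scatter @ x.data, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g[seg_ids])

    out._backward = bw
    return out


def weighted_neighbor_sum(
    alpha: Tensor,
    h: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    scatter_src: sparse.csr_matrix,
    scatter_dst: sparse.csr_matrix,
    head_dim: int,
) -> Tensor:
    """Fused attention aggregation: sum_j alpha_ij * h_j per destination node.

    ``alpha``: (E, heads) attention weights; ``h``: (N, heads*head_dim) node
    features; each head's weight multiplies its own ``head_dim`` columns.
    Equivalent to gather-multiply-scatter but with one op on the tape.
    """
    e, n_heads = alpha.shape
    alpha_rep = np.repeat(alpha.data, head_dim, axis=1)  # (E, heads*d)
    h_src = h.data[src]
    msg = alpha_rep * h_src
    out = Tensor(scatter_dst @ msg, parents=(alpha, h))

    def bw(g):
        gmsg = g[dst]
        if h.requires_grad:
            h._accumulate(scatter_src @ (gmsg * alpha_rep))
        if alpha.requires_grad:
            galpha = (gmsg * h_src).reshape(e, n_heads, head_dim).sum(axis=2)
            alpha._accumulate(galpha)

    out._backward = bw
    return out


def graph_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    alpha: Tensor,
    scatter: sparse.csr_matrix,
    membership: np.ndarray,
    inv_counts: np.ndarray,
    eps: float = 1e-5,
) -> Tensor:
    """Fused per-graph standardisation with learnable mean scale.

    ``y = gamma * (x - alpha*mu_g) / sqrt(var_g + eps) + beta`` where
    ``mu_g`` is the per-graph feature mean and ``var_g`` the per-graph mean
    square of the alpha-centred features.  ``scatter`` sums node rows per
    graph, ``membership`` maps nodes to graphs, ``inv_counts`` is the
    per-graph ``1/n_g`` column.  One tape node instead of ten.
    """
    mu = (scatter @ x.data) * inv_counts  # (G, F)
    xc = x.data - alpha.data * mu[membership]
    var = (scatter @ (xc * xc)) * inv_counts
    inv_std = 1.0 / np.sqrt(var + np.asarray(eps, dtype=x.data.dtype))
    xhat = xc * inv_std[membership]
    out = Tensor(gamma.data * xhat + beta.data, parents=(x, gamma, beta, alpha))

    def bw(gy):
        if beta.requires_grad:
            beta._accumulate(gy.sum(axis=0))
        if gamma.requires_grad:
            gamma._accumulate((gy * xhat).sum(axis=0))
        need_x = x.requires_grad
        need_a = alpha.requires_grad
        if not (need_x or need_a):
            return
        g1 = gy * gamma.data  # dL/dxhat
        # through the variance: var_g = mean of xc^2
        gvar = (scatter @ (g1 * xc)) * (-0.5) * inv_std**3
        gxc = g1 * inv_std[membership] + xc * (2.0 * gvar * inv_counts)[membership]
        sum_gxc = scatter @ gxc  # (G, F)
        if need_a:
            alpha._accumulate(-(sum_gxc * mu).sum(axis=0))
        if need_x:
            gmu = -alpha.data * sum_gxc
            x._accumulate(gxc + (gmu * inv_counts)[membership])

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = bw
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation).

    ``x``: (B, C_in, L); ``weight``: (C_out, C_in, K) with K odd;
    ``bias``: (C_out,).  Output: (B, C_out, L).
    """
    B, C_in, L = x.shape
    C_out, C_in_w, K = weight.shape
    if C_in_w != C_in:
        raise ValueError(f"channel mismatch: input {C_in}, kernel {C_in_w}")
    if K % 2 != 1:
        raise ValueError("kernel width must be odd for same padding")
    p = (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C_in,L,K)
    y = np.einsum("bclk,ock->bol", win, weight.data) + bias.data[None, :, None]
    out = Tensor(y, parents=(x, weight, bias))

    def bw(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            weight._accumulate(np.einsum("bclk,bol->ock", win, g))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
            win2 = np.lib.stride_tricks.sliding_window_view(gp, K, axis=2)
            gxp = np.einsum("bomk,ock->bcm", win2, weight.data[:, :, ::-1])
            x._accumulate(gxp[:, :, p : p + L])

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accumulate(g * (s - t) / z.size)

    out._backward = bw
    return out
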