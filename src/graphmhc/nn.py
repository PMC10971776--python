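"""The GraphMHC network: stacked graph attention + 1-D convolution head.

Architecture, applied to a minibatch of disconnected MHC-peptide graphs:

1. Four multi-head graph-attention layers.  For destination node i and
   in-neighbour j (self-loops included), the unnormalised attention is
   ``e_ij = LeakyReLU(a_dst . W h_i + a_src . W h_j + a_e . E_ij)``,
   softmax-normalised over j; messages ``W h_j`` are averaged with those
   weights, heads are concatenated, a bias is added, then ELU and graph
   normalisation (per-graph standardisation with a learnable mean scale).
   Attention weights are dropped out at rate ``dropout`` during training.
2. Mean readout over each graph's nodes.  The per-graph mean is the point
   where the two disconnected components (MHC and peptide) are mixed, and
   graph normalisation lets earlier layers see cross-component statistics.
3. The pooled vector is treated as a one-channel sequence: Conv1D ->
   BatchNorm -> ReLU -> Conv1D (same padding), with the head's input added
   to the second convolution's output (identity skip), then average pooling
   (width 2, stride 2).
4. A fully-connected layer produces the binding logit; sigmoid gives the
   probability.

Every tensor operation runs on the package's reverse-mode autodiff engine;
gather/scatter over edges and per-graph reductions are fancy-indexing
gathers paired with precomputed sparse scatter-add operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Tensor,
    bce_with_logits,
    conv1d,
    gather_rows,
    graph_norm,
    scatter_matrix,
    segment_sum,
    weighted_neighbor_sum,
)
from .data import GraphBatch

__all__ = ["ModelConfig", "GraphMHCNetwork", "Adam"]


@dataclass
class ModelConfig:
    """Layer hyperparameters of the GraphMHC architecture.

    The printed protocol fixes 4 attention layers, 8 heads and dropout 0.1;
    hidden widths are configuration choices.  ``conv_layers=0`` removes the
    convolution head (readout feeds the classifier directly), giving the
    attention-only ablation.
    """

    gat_layers: int = 4
    attention_heads: int = 8
    gat_hidden: int = 32  # per-head width
    conv_layers: int = 2
    conv_channels: int = 16
    conv_kernel: int = 3
    dropout: float = 0.1
    use_edge_features: bool = True

    def __post_init__(self):
        if min(self.gat_layers, self.attention_heads, self.gat_hidden) < 1:
            raise ValueError("layer counts and widths must be positive")
        if self.conv_layers not in (0, 2):
            raise ValueError("conv head is either present (2 layers) or absent (0)")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv kernel width must be odd")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if (self.attention_heads * self.gat_hidden) % 2 != 0:
            raise ValueError("attention_heads * gat_hidden must be even (pooling)")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class _BatchConstants:
    """Precomputed index plans for one batch's gather/scatter (self-loops included).

    Edges are sorted by destination node (so per-destination maxima are
    contiguous ``reduceat`` segments); gathers are fancy-indexing and their
    adjoint scatter-adds are precomputed sparse CSR operators.  Self-loops
    guarantee every node has an in-edge, and node rows arrive grouped by
    graph for the readout.
    """

    def __init__(self, batch: GraphBatch, dtype=np.float64):
        n = batch.num_nodes
        loops = np.arange(n, dtype=np.int64)
        src = np.concatenate([batch.edge_index[0], loops])
        dst = np.concatenate([batch.edge_index[1], loops])
        efeat = np.concatenate(
            [
                batch.edge_features.astype(dtype),
                np.zeros((n, batch.edge_features.shape[1]), dtype=dtype),
            ],
            axis=0,
        )
        order = np.argsort(dst, kind="stable")
        self.src = src[order]
        self.dst = dst[order]
        self.edge_features = Tensor(efeat[order])
        # every node has a self-loop, so no destination segment is empty
        self.dst_starts = np.searchsorted(self.dst, np.arange(n))
        self.scatter_src = scatter_matrix(self.src, n, dtype)
        self.scatter_dst = scatter_matrix(self.dst, n, dtype)
        self.membership = batch.graph_membership
        self.scatter_graph = scatter_matrix(self.membership, batch.num_graphs, dtype)
        self.inv_counts = (1.0 / batch.node_counts)[:, None].astype(dtype)
        self.dtype = dtype
        self.num_nodes = n
        self.num_graphs = batch.num_graphs

    # edge-level gathers and their transposed scatters ------------------
    def gather_src(self, x: Tensor) -> Tensor:
        return gather_rows(x, self.src, self.scatter_src)

    def gather_dst(self, x: Tensor) -> Tensor:
        return gather_rows(x, self.dst, self.scatter_dst)

    def scatter_to_dst(self, edge_values: Tensor) -> Tensor:
        return segment_sum(edge_values, self.scatter_dst, self.dst)

    # per-graph reductions ----------------------------------------------
    def graph_mean(self, x: Tensor) -> Tensor:
        total = segment_sum(x, self.scatter_graph, self.membership)
        return total * Tensor(self.inv_counts)

    def per_node(self, per_graph: Tensor) -> Tensor:
        return gather_rows(per_graph, self.membership, self.scatter_graph)


class GraphMHCNetwork:
    """Parameter container and forward pass of the GraphMHC model."""

    def __init__(
        self,
        config: ModelConfig,
        in_dim: int = 31,
        edge_dim: int = 12,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.in_dim = in_dim
        self.edge_dim = edge_dim
        self.dtype = np.dtype(dtype).type
        h, d = config.attention_heads, config.gat_hidden
        width = h * d
        self.params: dict[str, Tensor] = {}

        # mask confining the attention projections to their own head's block
        mask = np.zeros((width, h))
        for k in range(h):
            mask[k * d : (k + 1) * d, k] = 1.0
        self._head_mask = Tensor(mask.astype(self.dtype))

        dim = in_dim
        for layer in range(config.gat_layers):
            self._add(f"gat{layer}.W", _glorot(rng, (dim, width)))
            self._add(f"gat{layer}.b", np.zeros(width))
            self._add(f"gat{layer}.a_src", _glorot(rng, (width, h)) * mask)
            self._add(f"gat{layer}.a_dst", _glorot(rng, (width, h)) * mask)
            self._add(f"gat{layer}.a_edge", _glorot(rng, (edge_dim, h)))
            self._add(f"gat{layer}.gn_gamma", np.ones(width))
            self._add(f"gat{layer}.gn_beta", np.zeros(width))
            # mean-scale below 1: with alpha exactly 1 the per-graph mean of
            # the normalised features is identically beta, and the mean
            # readout would start blind to the graph
            self._add(f"gat{layer}.gn_alpha", np.full(width, 0.5))
            dim = width

        if config.conv_layers:
            c, k = config.conv_channels, config.conv_kernel
            self._add("conv1.W", _glorot(rng, (c, 1, k)))
            self._add("conv1.b", np.zeros(c))
            self._add("bn.gamma", np.ones(c))
            self._add("bn.beta", np.zeros(c))
            self._add("conv2.W", _glorot(rng, (1, c, k)))
            self._add("conv2.b", np.zeros(1))
            fc_in = width // 2
        else:
            fc_in = width
        self._add("fc.W", _glorot(rng, (fc_in, 1)))
        self._add("fc.b", np.zeros(1))

        self.bn_running_mean = np.zeros(config.conv_channels)
        self.bn_running_var = np.ones(config.conv_channels)
        self.bn_momentum = 0.1

    def _add(self, name: str, value: np.ndarray):
        self.params[name] = Tensor(value.astype(self.dtype), requires_grad=True)

    # ------------------------------------------------------------------
    def gat_layer(
        self,
        layer: int,
        x: Tensor,
        const: _BatchConstants,
        training: bool,
        rng: np.random.Generator | None,
    ) -> Tensor:
        p = self.params
        cfg = self.config
        Hn = x @ p[f"gat{layer}.W"]  # (N, heads*d)
        n_src = Hn @ (p[f"gat{layer}.a_src"] * self._head_mask)  # (N, heads)
        n_dst = Hn @ (p[f"gat{layer}.a_dst"] * self._head_mask)
        scores = const.gather_dst(n_dst) + const.gather_src(n_src)
        if cfg.use_edge_features:
            scores = scores + const.edge_features @ p[f"gat{layer}.a_edge"]
        scores = scores.leaky_relu(0.2)  # (E, heads)

        # softmax over each destination's in-neighbourhood (numerically
        # stabilised by the per-destination maximum, a constant shift)
        seg_max = np.maximum.reduceat(scores.data, const.dst_starts, axis=0)
        ex = (scores - Tensor(seg_max[const.dst])).exp()
        denom = const.scatter_to_dst(ex)  # (N, heads)
        alpha = ex / const.gather_dst(denom)
        if training and cfg.dropout > 0.0:
            keep = 1.0 - cfg.dropout
            mask = ((rng.random(alpha.shape) < keep) / keep).astype(alpha.data.dtype)
            alpha = alpha * Tensor(mask)

        out = weighted_neighbor_sum(
            alpha,
            Hn,
            const.src,
            const.dst,
            const.scatter_src,
            const.scatter_dst,
            cfg.gat_hidden,
        )
        out = out + p[f"gat{layer}.b"]
        out = out.elu()
        return self._graph_norm(layer, out, const)

    def _graph_norm(self, layer: int, x: Tensor, const: _BatchConstants) -> Tensor:
        p = self.params
        return graph_norm(
            x,
            p[f"gat{layer}.gn_gamma"],
            p[f"gat{layer}.gn_beta"],
            p[f"gat{layer}.gn_alpha"],
            const.scatter_graph,
            const.membership,
            const.inv_counts.reshape(-1, 1),
        )

    def conv_head(
        self, pooled: Tensor, training: bool, rng: np.random.Generator | None
    ) -> Tensor:
        """Conv1D -> BN -> ReLU -> Conv1D with identity skip, pool, FC."""
        p = self.params
        cfg = self.config
        g, width = pooled.shape
        x = pooled.reshape(g, 1, width)
        h1 = conv1d(x, p["conv1.W"], p["conv1.b"])  # (G, C, width)
        h1 = self._batch_norm(h1, training)
        h1 = h1.relu()
        if training and cfg.dropout > 0.0:
            keep = 1.0 - cfg.dropout
            mask = ((rng.random(h1.shape) < keep) / keep).astype(h1.data.dtype)
            h1 = h1 * Tensor(mask)
        h2 = conv1d(h1, p["conv2.W"], p["conv2.b"])  # (G, 1, width)
        h2 = h2 + x  # skip connection from the head's input
        pooled2 = h2.reshape(g, 1, width // 2, 2).mean(axis=3)
        flat = pooled2.reshape(g, width // 2)
        return (flat @ p["fc.W"] + p["fc.b"]).reshape(g)

    def _batch_norm(self, x: Tensor, training: bool) -> Tensor:
        p = self.params
        if training:
            mu = x.mean(axis=(0, 2), keepdims=True)  # (1, C, 1)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            m = self.bn_momentum
            self.bn_running_mean = (
                1 - m
            ) * self.bn_running_mean + m * mu.data.reshape(-1)
            n_stat = x.data.shape[0] * x.data.shape[2]
            unbiased = var.data.reshape(-1) * (n_stat / max(n_stat - 1, 1))
            self.bn_running_var = (1 - m) * self.bn_running_var + m * unbiased
        else:
            mu = Tensor(self.bn_running_mean.reshape(1, -1, 1).astype(self.dtype))
            var = Tensor(self.bn_running_var.reshape(1, -1, 1).astype(self.dtype))
            xc = x - mu
        xhat = xc / (var + 1e-5).sqrt()
        gamma = p["bn.gamma"].reshape(1, -1, 1)
        beta = p["bn.beta"].reshape(1, -1, 1)
        return xhat * gamma + beta

    def forward(
        self,
        batch: GraphBatch,
        training: bool = False,
        rng: np.random.Generator | None = None,
        const: _BatchConstants | None = None,
    ) -> Tensor:
        """Per-graph binding logits for one batch."""
        if training and self.config.dropout > 0.0 and rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")
        if const is None:
            const = _BatchConstants(batch, dtype=self.dtype)
        x = Tensor(batch.node_features.astype(self.dtype))
        for layer in range(self.config.gat_layers):
            x = self.gat_layer(layer, x, const, training, rng)
        pooled = const.graph_mean(x)  # mean readout, (G, heads*d)
        if self.config.conv_layers:
            return self.conv_head(pooled, training, rng)
        if training and self.config.dropout > 0.0:
            keep = 1.0 - self.config.dropout
            mask = ((rng.random(pooled.shape) < keep) / keep).astype(pooled.data.dtype)
            pooled = pooled * Tensor(mask)
        p = self.params
        return (pooled @ p["fc.W"] + p["fc.b"]).reshape(pooled.shape[0])

    def predict_proba(self, batch: GraphBatch) -> np.ndarray:
        """Evaluation-mode binding probabilities, shape (num_graphs,)."""
        return self.forward(batch, training=False).sigmoid().data

    def loss(
        self,
        batch: GraphBatch,
        training: bool = True,
        rng: np.random.Generator | None = None,
        const: _BatchConstants | None = None,
    ) -> Tensor:
        if batch.labels is None:
            raise ValueError("batch has no labels")
        logits = self.forward(batch, training=training, rng=rng, const=const)
        return bce_with_logits(logits, batch.labels)

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: t.data.copy() for name, t in self.params.items()}
        state["bn_running_mean"] = self.bn_running_mean.copy()
        state["bn_running_var"] = self.bn_running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, t in self.params.items():
            t.data = np.asarray(state[name], dtype=self.dtype)
        self.bn_running_mean = np.asarray(state["bn_running_mean"], dtype=np.float64)
        self.bn_running_var = np.asarray(state["bn_running_var"], dtype=np.float64)


class Adam:
    """ADAM optimizer over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
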