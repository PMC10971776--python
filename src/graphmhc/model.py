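"""GraphMHCClassifier: an sklearn-style estimator over featurized graphs.

Training follows the published protocol: minibatch binary cross-entropy with
the ADAM optimizer, batch size 64, 100 epochs, 8 attention heads, dropout
0.1.  Hidden widths and the training length are configuration parameters so
the same estimator scales from desk-size benchmarks to full tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import _make_batch, batch_graphs
from .featurize import GraphSample
from .nn import Adam, GraphMHCNetwork, ModelConfig, _BatchConstants

__all__ = ["GraphMHCClassifier", "train_model"]


class TrainingDivergedError(RuntimeError):
    pass


class GraphMHCClassifier(ClassifierMixin, BaseEstimator):
    """Binary MHC-peptide binding classifier on disconnected molecular graphs.

    Parameters mirror the architecture (4 graph-attention layers, 8 heads,
    two Conv1D layers with a skip connection) and the training protocol
    (ADAM, batch 64, 100 epochs, dropout 0.1).  ``conv_layers=0`` yields the
    attention-only ablation.

    Attributes (after :meth:`fit`)
    ------------------------------
    network_ : GraphMHCNetwork
        The trained parameter container.
    loss_history_ : list[float]
        Mean training loss per epoch.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        gat_layers: int = 4,
        attention_heads: int = 8,
        gat_hidden: int = 32,
        conv_layers: int = 2,
        conv_channels: int = 16,
        conv_kernel: int = 3,
        dropout: float = 0.1,
        use_edge_features: bool = True,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 100,
        random_state: int = 0,
        verbose: int = 0,
        precision: str = "float32",
    ):
        self.gat_layers = gat_layers
        self.attention_heads = attention_heads
        self.gat_hidden = gat_hidden
        self.conv_layers = conv_layers
        self.conv_channels = conv_channels
        self.conv_kernel = conv_kernel
        self.dropout = dropout
        self.use_edge_features = use_edge_features
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state
        self.verbose = verbose
        self.precision = precision

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            gat_layers=self.gat_layers,
            attention_heads=self.attention_heads,
            gat_hidden=self.gat_hidden,
            conv_layers=self.conv_layers,
            conv_channels=self.conv_channels,
            conv_kernel=self.conv_kernel,
            dropout=self.dropout,
            use_edge_features=self.use_edge_features,
        )

    @staticmethod
    def _check_samples(X, y=None) -> list[GraphSample]:
        samples = list(X)
        if not samples:
            raise ValueError("empty sample list")
        for k, s in enumerate(samples):
            if not isinstance(s, GraphSample):
                raise TypeError(f"X[{k}] is {type(s).__name__}, expected GraphSample")
        if y is not None:
            y = np.asarray(y)
            if len(y) != len(samples):
                raise ValueError("X and y length mismatch")
            if not set(np.unique(y)) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")
            samples = [
                GraphSample(s.node_features, s.edge_index, s.edge_features,
                            label=int(t), group_id=s.group_id)
                for s, t in zip(samples, y)
            ]
        elif any(s.label is None for s in samples):
            raise ValueError("samples carry no labels and y was not given")
        return samples

    def fit(self, X, y=None):
        """Train on a list of :class:`GraphSample` (labels from ``y`` or the samples)."""
        samples = self._check_samples(X, y)
        rng = np.random.default_rng(self.random_state)
        config = self._model_config()
        in_dim = samples[0].node_features.shape[1]
        edge_dim = samples[0].edge_features.shape[1]
        dtype = np.dtype(self.precision)
        if dtype.kind != "f":
            raise ValueError(f"precision must be a float dtype, got {self.precision!r}")
        self.network_ = GraphMHCNetwork(
            config, in_dim=in_dim, edge_dim=edge_dim, rng=rng, dtype=dtype
        )
        optimizer = Adam(self.network_.params, lr=self.learning_rate)

        order = rng.permutation(len(samples))
        shuffled = [samples[i] for i in order]
        batches = list(batch_graphs(shuffled, self.batch_size))
        constants = [_BatchConstants(b, dtype=self.network_.dtype) for b in batches]

        self.loss_history_ = []
        for epoch in range(self.epochs):
            epoch_order = rng.permutation(len(batches))
            losses = []
            for bi in epoch_order:
                optimizer.zero_grad()
                loss = self.network_.loss(
                    batches[bi], training=True, rng=rng, const=constants[bi]
                )
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch + 1}: {loss.data!r}"
                    )
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            self.loss_history_.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}: loss {self.loss_history_[-1]:.4f}")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = in_dim
        return self

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        samples = self._check_samples_unlabelled(X)
        out = []
        for batch in batch_graphs(samples, self.batch_size):
            out.append(self.network_.forward(batch, training=False).data)
        return np.concatenate(out)

    @staticmethod
    def _check_samples_unlabelled(X) -> list[GraphSample]:
        samples = list(X)
        if not samples:
            raise ValueError("empty sample list")
        for k, s in enumerate(samples):
            if not isinstance(s, GraphSample):
                raise TypeError(f"X[{k}] is {type(s).__name__}, expected GraphSample")
        return samples

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability matrix of shape ``(n, 2)``; column 1 is binding."""
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_single(self, sample: GraphSample) -> float:
        """Binding probability of one graph."""
        batch = _make_batch([sample])
        return float(self.network_.predict_proba(batch)[0])

    # ------------------------------------------------------------------
    def save(self, path):
        """Write parameters (npz) and a JSON config sidecar (``<path>.json``)."""
        check_is_fitted(self, "network_")
        path = Path(path)
        np.savez_compressed(path, **self.network_.state_dict())
        sidecar = {
            "params": self.get_params(),
            "loss_history": self.loss_history_,
            "in_dim": int(self.n_features_in_),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GraphMHCClassifier":
        path = Path(path)
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        est = cls(**sidecar["params"])
        with np.load(path) as z:
            state = {k: z[k] for k in z.files}
        est.network_ = GraphMHCNetwork(
            est._model_config(), in_dim=sidecar["in_dim"],
            rng=np.random.default_rng(0), dtype=np.dtype(est.precision),
        )
        est.network_.load_state_dict(state)
        est.loss_history_ = list(sidecar["loss_history"])
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = sidecar["in_dim"]
        return est


def train_model(samples, **params) -> GraphMHCClassifier:
    """Functional wrapper: train a :class:`GraphMHCClassifier` on labelled samples."""
    return GraphMHCClassifier(**params).fit(samples)
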