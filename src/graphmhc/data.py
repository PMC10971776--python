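"""Affinity tables, pseudo-sequence maps, splitting and graph batching.

Binding labels follow the standard quantitative rule: a peptide is called a
binder when its assay IC50 is at most 500 nM, a non-binder above 500 nM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .featurize import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, GraphSample

__all__ = [
    "BINDING_THRESHOLD_NM",
    "BindingRecord",
    "binding_label",
    "read_pseudosequence_map",
    "read_affinity_table",
    "split_train_test",
    "GraphBatch",
    "batch_graphs",
    "unbatch",
    "save_graph_dataset",
    "load_graph_dataset",
]

logger = logging.getLogger(__name__)

BINDING_THRESHOLD_NM = 500.0


@dataclass(frozen=True)
class BindingRecord:
    allele: str
    peptide: str
    ic50: float
    label: int

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50}")


def binding_label(ic50: float) -> int:
    """1 (binder) iff IC50 <= 500 nM, else 0."""
    return int(ic50 <= BINDING_THRESHOLD_NM)


def read_pseudosequence_map(path) -> dict[str, str]:
    """Read a whitespace-delimited allele -> pseudo-sequence table.

    Lines starting with ``#`` are comments.  All pseudo-sequences must share
    one length (34 for the standard NetMHCpan-style binding-groove residues;
    synthetic maps may use a shorter uniform length).
    """
    mapping: dict[str, str] = {}
    lengths = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'allele pseudo-sequence'")
            allele, pseudo = parts[0], parts[1]
            mapping[allele] = pseudo
            lengths.add(len(pseudo))
    if len(lengths) > 1:
        raise ValueError(
            f"{path}: inconsistent pseudo-sequence lengths {sorted(lengths)}"
        )
    return mapping


def read_affinity_table(
    path,
    mapping: dict[str, str] | None = None,
    allele_col: str = "allele",
    peptide_col: str = "peptide",
    ic50_col: str = "ic50",
) -> tuple[list[BindingRecord], int]:
    """Read an IEDB-style quantitative affinity CSV.

    Labels are assigned by the 500 nM rule.  When ``mapping`` is given, rows
    whose allele has no pseudo-sequence are dropped and counted (the count is
    also logged), mirroring the exclusion of alleles without conversion data.

    Returns ``(records, n_dropped)``.
    """
    df = pd.read_csv(path)
    missing = [c for c in (allele_col, peptide_col, ic50_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    ic50 = pd.to_numeric(df[ic50_col], errors="coerce")
    bad = ic50.isna() | (ic50 <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric or non-positive IC50 {df[ic50_col].iloc[row]!r} "
            f"in data row {row + 1}"
        )
    records: list[BindingRecord] = []
    n_dropped = 0
    for allele, peptide, value in zip(df[allele_col], df[peptide_col], ic50):
        if mapping is not None and allele not in mapping:
            n_dropped += 1
            continue
        records.append(
            BindingRecord(
                allele=str(allele),
                peptide=str(peptide),
                ic50=float(value),
                label=binding_label(float(value)),
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d/%d rows with alleles absent from the pseudo-sequence map",
            n_dropped,
            len(df),
        )
    return records, n_dropped


def split_train_test(records, train_fraction: float = 0.8, seed: int = 0):
    """Random (non-stratified) train/test partition.

    Deterministic under a fixed seed; the train size is the floor of
    ``train_fraction * N`` (within one record of exact proportions; a table
    of 157 084 rows splits 125 667 / 31 417 at the default 80%).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot split an empty record list")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    train, test = train_test_split(
        records, train_size=train_fraction, random_state=seed, shuffle=True
    )
    return train, test


@dataclass
class GraphBatch:
    """A minibatch of graphs concatenated into one block-diagonal graph.

    ``graph_membership[k]`` is the within-batch graph index of node ``k``;
    ``edge_index`` is offset by cumulative node counts and sorted by
    destination node so per-node segment reductions are contiguous.
    """

    node_features: np.ndarray  # (total_nodes, 31)
    edge_index: np.ndarray  # (2, total_directed_edges)
    edge_features: np.ndarray  # (total_directed_edges, 12)
    graph_membership: np.ndarray  # (total_nodes,)
    node_counts: np.ndarray  # (num_graphs,)
    labels: np.ndarray | None  # (num_graphs,) or None

    @property
    def num_graphs(self) -> int:
        return len(self.node_counts)

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]


def _make_batch(samples: list[GraphSample]) -> GraphBatch:
    counts = np.array([s.num_nodes for s in samples], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    x = np.concatenate([s.node_features for s in samples], axis=0)
    ei = np.concatenate(
        [s.edge_index + off for s, off in zip(samples, offsets)], axis=1
    )
    ef = np.concatenate([s.edge_features for s in samples], axis=0)
    # stable sort by destination keeps the per-graph source order reproducible
    order = np.argsort(ei[1], kind="stable")
    ei = ei[:, order]
    ef = ef[order]
    membership = np.repeat(np.arange(len(samples), dtype=np.int64), counts)
    labels = None
    if all(s.label is not None for s in samples):
        labels = np.array([s.label for s in samples], dtype=np.float64)
    return GraphBatch(
        node_features=x,
        edge_index=ei,
        edge_features=ef,
        graph_membership=membership,
        node_counts=counts,
        labels=labels,
    )


def batch_graphs(samples, batch_size: int = 64):
    """Yield :class:`GraphBatch` minibatches of at most ``batch_size`` graphs."""
    samples = list(samples)
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    for start in range(0, len(samples), batch_size):
        yield _make_batch(samples[start : start + batch_size])


def unbatch(batch: GraphBatch) -> list[GraphSample]:
    """Recover per-graph tensors from a batch (inverse of batching).

    Edge order within each graph may differ from the original sample; edges
    are returned sorted by (destination, source).
    """
    out = []
    offsets = np.concatenate([[0], np.cumsum(batch.node_counts)])
    for g in range(batch.num_graphs):
        lo, hi = offsets[g], offsets[g + 1]
        mask = (batch.edge_index[1] >= lo) & (batch.edge_index[1] < hi)
        ei = batch.edge_index[:, mask] - lo
        ef = batch.edge_features[mask]
        order = np.lexsort((ei[0], ei[1]))
        out.append(
            GraphSample(
                node_features=batch.node_features[lo:hi].copy(),
                edge_index=ei[:, order],
                edge_features=ef[order],
                label=None if batch.labels is None else int(batch.labels[g]),
            )
        )
    return out


def save_graph_dataset(samples: list[GraphSample], path, manifest: dict | None = None):
    """Serialize featurized graphs to ``<path>`` (npz) + ``<path>.json`` manifest."""
    path = Path(path)
    node_counts = np.array([s.num_nodes for s in samples], dtype=np.int64)
    edge_counts = np.array([s.num_edges for s in samples], dtype=np.int64)
    labels = np.array(
        [-1 if s.label is None else s.label for s in samples], dtype=np.int64
    )
    np.savez_compressed(
        path,
        node_features=np.concatenate([s.node_features for s in samples], axis=0),
        edge_index=np.concatenate([s.edge_index for s in samples], axis=1),
        edge_features=np.concatenate([s.edge_features for s in samples], axis=0),
        node_counts=node_counts,
        edge_counts=edge_counts,
        labels=labels,
    )
    meta = {
        "num_samples": len(samples),
        "node_feature_dim": NODE_FEATURE_DIM,
        "edge_feature_dim": EDGE_FEATURE_DIM,
    }
    if manifest:
        meta.update(manifest)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_graph_dataset(path) -> list[GraphSample]:
    with np.load(path) as z:
        node_counts = z["node_counts"]
        edge_counts = z["edge_counts"]
        labels = z["labels"]
        x = z["node_features"]
        ei = z["edge_index"]
        ef = z["edge_features"]
    samples = []
    n_off = 0
    e_off = 0
    for k, (nc, ec) in enumerate(zip(node_counts, edge_counts)):
        samples.append(
            GraphSample(
                node_features=x[n_off : n_off + nc],
                edge_index=ei[:, e_off : e_off + ec],
                edge_features=ef[e_off : e_off + ec],
                label=None if labels[k] < 0 else int(labels[k]),
            )
        )
        n_off += nc
        e_off += ec
    return samples
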