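# graphmhc

Neoantigen prediction as molecular graph classification: an MHC class-I
binding-groove pseudo-sequence and a candidate 9-mer peptide are built as
explicit-hydrogen molecules, joined as the two disconnected components of a
single graph (the SMILES `.` construction), and classified as binding
(IC50 ≤ 500 nM) or non-binding by a stacked graph-attention +
1-D-convolution network.  A downstream module turns per-patient missense
variants into neoantigen loads and compares high/low-load groups by overall
survival (log-rank) and biomarker scores (rank-sum).

The package is aimed at computational immunologists and method developers
who want a self-contained, CPU-trainable reimplementation of this pipeline
with planted-truth synthetic data for every stage.

## The model

Atoms carry 31 one-hot chemical features (element, hybridisation, degree,
bonded hydrogens, chirality, aromaticity, ring membership, formal charge,
radicals) and bonds carry 12 (type, stereo, ring, conjugation).  Four
multi-head graph-attention layers compute, for atom *i* with in-neighbour
*j*,

    e_ij = LeakyReLU(a_dst·W h_i + a_src·W h_j + a_e·E_ij),
    α_ij = softmax_j(e_ij),      h'_i = ELU( Σ_j α_ij W h_j ),

followed by graph normalisation; a mean readout pools each graph; two 1-D
convolutions with an identity skip, average pooling and a sigmoid
fully-connected layer produce P(binding).  Training uses binary
cross-entropy with ADAM (batch 64, dropout 0.1, 8 heads by default).  The
network and its gradients run on a small NumPy reverse-mode autodiff engine
— no deep-learning framework required.

Neoantigen load: for each patient, every 9-mer window containing a mutated
residue is paired with each of the patient's alleles; the load is the
number of pairs with predicted P(binding) ≥ 0.5.  The cohort is split at
the median load and compared with the Mantel–Cox log-rank test (optionally
censored at 5 years) and two-sided Mann–Whitney tests on stromal / immune /
ESTIMATE scores.

## Worked example

```python
import numpy as np
from graphmhc import (
    SynthConfig, generate_affinity_dataset, featurize_pair,
    split_train_test, GraphMHCClassifier, evaluate_scores,
)

# synthetic IEDB-style table: 10 alleles, planted anchor rule at {2, 9}
data = generate_affinity_dataset(
    SynthConfig(n_records=2500, pseudo_length=4, seed=11)
)
samples = [
    featurize_pair(data.pseudo_map[r.allele], r.peptide, label=int(r.label))
    for r in data.records.itertuples()
]
train, test = split_train_test(samples, 0.8, seed=11)

clf = GraphMHCClassifier(
    attention_heads=4, gat_hidden=4, conv_channels=8,  # desk-scale widths
    dropout=0.0, learning_rate=1e-2, epochs=50, random_state=11,
).fit(train)

y = np.array([s.label for s in test])
report = evaluate_scores(clf.predict_proba(test)[:, 1], y)
print(f"AUC {report.auc:.3f}  CI [{report.auc_ci[0]:.3f}, {report.auc_ci[1]:.3f}]")
print(f"sens {report.sensitivity:.3f}  spec {report.specificity:.3f}  F1 {report.f1:.3f}")
```

Typical output (seed-dependent):

```
AUC 0.937  CI [0.914, 0.959]
sens 0.851  spec 0.890  F1 0.870
```

The AUC is the probability that a random true binder outscores a random
non-binder (DeLong 95% interval); sensitivity/specificity/F1 are taken at
the 0.5 probability threshold.  Values near 0.5 would mean the planted
anchor rule was not learned; values near 1 that the network recovered it.

The same pipeline is scriptable from the shell:

```bash
graphmhc synth --seed 3 --out-dir data/
graphmhc featurize --affinity data/affinity.csv --pseudo-map data/pseudo.map --out ds.npz
graphmhc train --dataset ds.npz --out model.npz --epochs 30
graphmhc evaluate --model model.npz --dataset ds.npz --out report.json
graphmhc neoload --model model.npz --pseudo-map data/pseudo.map \
    --patients data/patients.csv --clinical data/clinical.csv --out-dir neo/
```

## Layout

| Path | Contents |
| --- | --- |
| `src/graphmhc/chem.py` | residue templates, peptide assembly, SMILES I/O |
| `src/graphmhc/featurize.py` | 31/12-dim graph featurization, ring perception |
| `src/graphmhc/data.py` | affinity tables, pseudo-sequence maps, split, batching |
| `src/graphmhc/autodiff.py` | reverse-mode autodiff engine |
| `src/graphmhc/nn.py` | GAT layers, GraphNorm, convolution head, ADAM |
| `src/graphmhc/model.py` | `GraphMHCClassifier` (sklearn-style estimator) |
| `src/graphmhc/metrics.py` | AUC, DeLong CI, Wilson/bootstrap intervals |
| `src/graphmhc/neoantigen.py` | 9-mer windows, loads, survival/biomarker tests |
| `src/graphmhc/synth.py` | planted-truth synthetic data generators |
| `src/graphmhc/cli.py` | `graphmhc` command-line interface |

See `docs/methods.md` for the modelling assumptions, the synthetic study
conditions and the numerical choices.
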