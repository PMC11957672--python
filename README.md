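# bindnode

Per-residue prediction of ligand binding — to **metal ions**, **nucleic
acids** and **small molecules** — from protein-language-model (pLM)
embeddings and predicted 3D structure, using lightweight graph neural
networks over residue contact graphs.

## The problem and the approach

Most residues in a protein never touch a ligand; the handful that do
determine catalysis, recognition and druggability, and experimental
annotations cover only a sliver of sequence space. Sequence-only
predictors map per-residue pLM embeddings to binding labels with
convolutional networks, ignoring the protein's geometry. Here the
predicted structure enters the model in the most economical way possible:
it is reduced to an L×L Cα distance map, thresholded at a cutoff *T* (Å)
into an undirected residue graph whose edges carry weights

&nbsp;&nbsp;&nbsp;&nbsp;w(i, j) = max(1 − d(i, j)/T, ε),

so spatially close residues exchange strong messages and residues near the
cutoff weak ones. At T = 4 Å the graph is exactly the backbone (Cα–Cα
spacing ≈ 3.8 Å), i.e. the sequence itself; the production configuration
uses T = 17 Å.

The production architecture is a two-layer weighted-mean **GraphSAGE**
network: for node features h,

&nbsp;&nbsp;&nbsp;&nbsp;h′ᵢ = W_self·hᵢ + W_nbr·(Σⱼ wᵢⱼ hⱼ / Σⱼ wᵢⱼ) + b,

with d → 128 → 3 dimensions, leaky-relu and 0.7 dropout between layers,
and an element-wise sigmoid producing three independent class
probabilities per residue (a residue may bind several ligand classes; it
is called binding to class C when p_C ≥ 0.5). Because the second graph
layer emits the 3 classes directly, the model has 2·1024·128+128 +
2·128·3+3 = **263,043** free parameters against **657,411** for the
reference two-layer sequence CNN (kernel 5, 1024→128→3) — a **59.99 %**
reduction at comparable accuracy. Three further architectures (two-layer
GCN, GraphSAGE+MLP, and a parallel GraphSAGE/GATv2 branch concatenating
to a 160-dim vector) are implemented for comparison, optionally
concatenating a 20-dimensional normalized DSSP feature vector (relative
position, 8-class secondary structure one-hot, φ/ψ, RSA, four H-bond
(relative index, energy) pairs).

Training is class-weighted binary cross-entropy (weights 8.9 / 7.7 / 4.4
for metal / nucleic / small positives, countering the ~90 % non-binding
imbalance), Adam, one protein graph per step, early stopping on validation
binary F1, 5-fold cross-training; the final predictor averages the five
fold models. Everything is seeded and bit-reproducible on CPU. The GNN
layers and their training run on a small numpy-based reverse-mode
autodiff engine included in the package.

Evaluation reports MCC, precision, recall, accuracy and F1 per ligand
class and for the binary binding/non-binding task, each computed per
protein and aggregated as mean ± 1.96·SE (95 % CI), plus PR/ROC sweeps,
reliability (max class probability) vs. precision tables, and the Pearson
correlation between pLDDT and predicted binding.

## Worked example

The package ships a synthetic-data generator that emulates every input:
random-walk Cα chains with realistic 3.8 Å spacing, spatial binding
pockets, embeddings with a plantable linear class signal, DSSP-like
records. On 50 synthetic proteins with a planted signal:

```python
from bindnode import BindingSiteModel, FixtureSpec, TrainConfig

model = BindingSiteModel.from_fixtures(FixtureSpec(n_proteins=50, seed=0))
results = model.fit(TrainConfig(seed=0, max_epochs=30, patience=10))
print(results.summary())
```

```
Binding-residue GNN results
================================================================
architecture:      SAGEConv
input dim:         64
free parameters:   17,283
distance cutoff:   17 A
proteins:          50
folds trained:     5
class weights:     (8.9, 7.7, 4.4)
----------------------------------------------------------------
task     metric         mean   ±95% CI     n
metal    mcc           0.887     0.058    28
...
binary   f1            0.891     0.034    50
================================================================
```

Each row is the per-protein mean of a confusion-matrix metric with its
95 % confidence half-width; `n` counts the proteins where the metric is
defined (proteins with neither observed nor predicted positives for a
class are excluded from that class's aggregate). The high numbers reflect
the planted, linearly separable synthetic signal — they say the pipeline
recovers a recoverable signal, not that real proteins are this easy.

The same pipeline is scriptable from the shell:

```bash
bindnode simulate --n 50 --seed 0 --out data/
bindnode train --data data/ --out run/          # SAGEConv, 17 Å by default
bindnode predict --data data/ --models run/ --out predictions.tsv
bindnode evaluate --predictions predictions.tsv --data data/ --out metrics.tsv
bindnode count-params --arch SAGEConv           # 263,043 vs 657,411 (−59.99 %)
bindnode sweep-thresholds --data data/ --out sweep.tsv
```

Real data plugs in through the same directory layout: single-chain
PDB/mmCIF predicted structures with pLDDT in the B-factor column, a FASTA
file, an HDF5 container of per-residue embeddings (one L×d float32
dataset per protein id; d = 768/1024/1536/2560 for the common pLMs),
label and split TSVs, and optional DSSP output files. Proteins whose
artifacts disagree on length are excluded up front and reported.

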