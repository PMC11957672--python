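# Methods

## Model

The predictor is a node-classification GNN over a per-protein residue
graph. Inputs per residue are a fixed pLM embedding x ∈ ℝᵈ (consumed
pre-computed; d ∈ {768, 1024, 1536, 2560} for the common pLMs, arbitrary
d accepted) and optionally a 20-dim normalized DSSP vector. The structure
contributes only through the graph: vertices are residues, edges are Cα
pairs with d(i,j) ≤ T, edge weights w = max(1 − d/T, ε) with ε = 1e-6.

Weighted-mean GraphSAGE layer:
h′ᵢ = W_self hᵢ + W_nbr mᵢ + b, with mᵢ = Σⱼ wᵢⱼ hⱼ / Σⱼ wᵢⱼ over the
neighbourhood, and mᵢ = 0 for isolated nodes (so the layer degenerates to
a linear map there). GCN uses the standard symmetric normalization
D^{-1/2}(A+I)D^{-1/2} with unit self-loops over the weighted adjacency.
GATv2 is single-head with bias: e_ij = aᵀ LeakyReLU(W_l hᵢ + W_r hⱼ),
softmax over N(i) ∪ {i}, output Σ α_ij W_r hⱼ + b; attention is not
edge-weighted (the thresholded neighbourhood already encodes the
geometry). Output activation is an element-wise sigmoid: the three class
probabilities are independent because multi-label calls are thresholded
per class at 0.5 (inclusive).

Architecture wiring (hidden width 128, dropout 0.7):

- **GCNConv**: gcn(d→128), relu, dropout, gcn(128→3).
- **SAGEConv** (production): sage(d→128), leaky-relu(0.01), dropout,
  sage(128→3). DSSP variant concatenates at the input: d+20 (1044 for
  d = 1024).
- **SAGEConvMLP**: sage(d→128), leaky-relu, [concat DSSP → 148],
  fc(→32), relu, dropout, fc(→3). The self-consistent widths are
  148→32→3; no 5-feature DSSP subset exists that would make the second FC
  input anything else, so the concat-at-FC-1 wiring is canonical here.
- **SAGEConvGATMLP**: sage(d→128) in parallel with
  sage((d or 20)→128) → gatv2(128→64) → gatv2(64→32); concat 128+32=160 →
  fc(160→32), relu, dropout, fc(32→3). The FC widths after the 160-dim
  concat are a package convention (160→32→3).

The two-layer models emit the 3 classes from the second graph layer with
no separate head; this wiring is what yields the 59.99 % parameter
reduction versus the reference CNN (two 1-D convolutions along the
sequence, kernel width 5, channels 1024→128→3, with biases — frozen in
`count_reference_cnn_parameters` so the comparison is reproducible).
Counts: SAGE layer 2·in·out+out, GCN in·out+out, GATv2 2·in·out+2·out,
FC in·out+out; closed forms are tested against enumeration of the
instantiated arrays.

## DSSP features (20 columns, all in [0, 1])

[relpos | ss one-hot H,B,E,G,I,T,S,- | φ | ψ | RSA | 4 H-bond rel. indices
| 4 H-bond energies]. relpos = i/L (1-based). Dihedrals map by
(angle+180)/360 — the affine completion that lands in [0, 1]; the DSSP
sentinel 360° (undefined at termini) maps to 0. RSA = ACC / Sander
max-ACC, clipped. The four (relative index, energy) pairs are DSSP's
NH→O(1), O→NH(1), NH→O(2), O→NH(2) backbone H-bond descriptors — the only
DSSP fields matching "relative indices and energies" — min-max normalized
per column within each protein; a constant column becomes zeros, and
min-max makes any sign/offset convention for the relative indices
immaterial (affine invariance is property-tested). Parsing of the classic
fixed-column format is delegated to biopython's `make_dssp_dict`; the
column order of the 20 features is a package convention frozen by tests.

## Training

Loss: mean over L×3 of class-weighted BCE, positive terms scaled by
(8.9, 7.7, 4.4) for (metal, nucleic, small). Computed from logits via
softplus identities for stability. Optimiser Adam (lr 1e-3, β = 0.9/0.999);
one protein graph per step (graphs are small, lengths vary); max 200
epochs, early stopping with patience 20 on validation binary F1
(threshold 0.5); the best-validation checkpoint is returned. These
optimisation details are package choices exposed in `TrainConfig`.
Cross-training: fold k of 5 trains on the other four folds; the final
predictor is the arithmetic mean of the five fold probability matrices.
All randomness (init, epoch shuffling, dropout masks) derives from
numpy PCG64 streams seeded from `TrainConfig.seed`, so runs are
bit-reproducible on a single worker.

The GNN layers and optimiser run on a small tape-based reverse-mode
autodiff engine over numpy arrays (`bindnode._autograd`), covering dense
matmul, elementwise nonlinearities, gather/scatter for edge-list
attention, and concatenation; gradients are verified against central
finite differences in the test suite.

## Evaluation

MCC, precision, recall, accuracy, F1 from per-residue confusion counts,
per ligand class and for the binary (any-class) task. Zero denominators
return 0, keeping every metric a total function. Aggregation follows the
per-protein protocol: metric per protein, then mean ± 1.96·SD/√n.
A protein with neither observed nor predicted positives for a class has
that class's metrics undefined and is excluded from that aggregate by
default (zero-filling is available but biases means for proteins lacking
a ligand class entirely); the count of contributing proteins is reported.
The binary reduction is the logical OR of the class calls with score =
max class probability, consistent with the per-class ≥0.5 rule and used
for PR/ROC sweeps and the reliability (coverage/precision above a score
cutoff) table. pLDDT–prediction association is the Pearson r; constant
inputs return NaN with a warning.

## Synthetic data

The generator produces what the method consumes, with the real data's
statistical shape but no pretence of physical realism:

- **Chains**: persistent self-avoiding random walks, consecutive Cα
  spacing exactly 3.8 Å, non-adjacent clearance > 4.5 Å (hence the 4 Å
  graph is exactly the backbone), backtracking when trapped. Geometry
  beyond spacing statistics is irrelevant because the model sees only
  distances.
- **Labels**: spatial pockets — all residues within 8 Å of each of 2
  pocket-centre Cαs share that pocket's class (uniform over the three
  classes by default). With lengths 80–120 this yields ~10 % binding
  residues, matching the ~90 % non-binding imbalance of the real corpus.
- **Embeddings**: x = s·Σ_c y_c μ_c + ε with orthogonal class directions
  μ_c (first three axes) and unit Gaussian noise. Default dimension 64:
  the signal is rank-3, so recoverability does not depend on d, and the
  smaller width keeps desk-scale runs fast. s = 3 is the default planted
  signal; s = 0 is the null model.
- **DSSP records and pLDDT** (uniform [50, 100]) are plausible fillers
  that exercise parsing/normalization, not structure-derived quantities.

Passing the planted-signal suite therefore shows the pipeline trains,
generalises and is correctly plumbed — not that real binding residues are
linearly separable in real embeddings; headline real-data accuracy
requires the curated experimental corpus and real pLM embeddings, which
are out of scope here.

## Problem sizes and numerical choices

The acceptance script trains on 100 synthetic proteins (80/20 split,
held-out evaluation on 20 more, ≤50 epochs) — sizes chosen as the
smallest at which recovery is stable across seeds. Graph/metric oracle
checks use 100 random chains (L ≤ 50) and all 14,640 confusion tables
with entries ≤ 10. Boundary edges at d = T are kept (robust to 3.8 Å
backbone rounding) with weight ε rather than dropped. Thresholds outside
1–20 Å warn but proceed. Checkpoints are .npz named-array containers with
a JSON config sidecar and round-trip bit-exactly.

## Known limitations

Single-chain monomers only (multi-chain files are rejected, not
concatenated); no embedding generation; no probability calibration; no
k-NN or all-atom contact definitions; CPU-oriented dense per-protein
message passing (adequate for chains of a few hundred residues, not for
complexes); the per-protein CI assumes approximate normality of the
metric distribution.
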