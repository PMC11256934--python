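# Methods

## Problem setting

The observed matrix `X_obs` is treated as a corrupted view of a ground
truth `X_gt`: technical dropout replaces true expression with zeros.
Benchmarking follows the masked matrix-completion convention: 10% of
the *nonzero* entries of `X_gt` are hidden as a test set and another
10% for validation (sizes `round(frac·Z)` with half-values rounded
down; sampling is uniform over nonzero entries without stratification),
the input matrix is `X_gt` with those entries zeroed, and imputation is
scored only at the hidden positions. True (structural) zeros are never
part of any mask, the loss, or the metrics.

Training and evaluation operate on library-size-normalised,
log1p-transformed values by default (per-cell scaling to 1e4 total —
the dominant convention; exact zeros remain exactly zero, so the
nonzero set and hence the masks are unchanged by normalisation).
Raw-scale operation is available with `normalize="none"`. Note one
deliberate simplification: normalisation is computed on the full matrix
before masking, as benchmark pipelines in this field usually do, so
per-cell library sizes include held-out entries; the leakage-protection
invariant is stated (and tested) at the level of normalised values.

## Graph construction

* Spatial graph: edge iff Euclidean distance ≤ `d_thr`. When `d_thr` is
  not given it is chosen as the smallest threshold reaching mean degree
  6 — the hexagonal-lattice neighbour count, matching Visium geometry.
* Gene-similarity graph: exact k-nearest neighbours (default `k = 6`)
  under Euclidean distance on the highly variable gene submatrix of the
  *masked* matrix (held-out values cannot shape the graph). The top-k
  relation is directed; the stored edge set is its symmetrised union so
  walks can traverse similarity links in both directions (standard kNN
  graph practice); the directed relation is kept for diagnostics.
  Distance ties are broken by ascending cell index, making builds
  deterministic. HVGs are ranked by plain dispersion (variance/mean)
  with index tie-breaks; the default of 3100 genes suits real panels,
  while synthetic runs use all or most genes.

## Walk sampling

Second-order node2vec walks: from the current node, weight `1/p` to
return to the previous node, `1` to a common neighbour of current and
previous, `1/q` outward, normalised over neighbours; the first step is
uniform. Defaults `q = p = 1` reduce to a first-order uniform walk (a
vectorised fast path). Walk length `k` counts **nodes** — a length-8
walk makes 7 hops — and position 1 is the start node, so every cell
contributes its own embedding to its update. A node with no neighbour
self-pads (the walk stays put). Each node starts exactly `T` walks per
graph per epoch; walks are drawn with replacement, duplicates allowed.
One walk set per graph is shared across layers within an epoch and
resampled every epoch through a collision-free `SeedSequence` schedule,
so full runs replay exactly from one base seed.

## Model

The central definitional choice: **path convolution is channel-wise**.
The operator is a `(k × d)` weight array and channel `j` of a path's
contribution is `Σ_i op[i, j]·f[P_i, j]` — a per-channel
multiply-accumulate over walk positions, averaged over the `T` walks.
(A reading that also sums over channels would collapse each path to a
scalar, which is incompatible with the next layer expecting a
`d`-dimensional embedding and with per-channel operator sharing; the
channel-wise form is the one under which all four sharing modes are
meaningful.)

Sharing modes tie the operator tensor across layers and/or channels;
channel-shared modes store a `(k, 1)` column broadcast across channels:

| mode   | across layers | across channels | operator weights            |
|--------|---------------|-----------------|-----------------------------|
| op_glo | shared        | shared          | `k_s + k_g`                 |
| op_cha | distinct      | shared          | `L·(k_s + k_g)`             |
| op_lay | shared        | distinct        | `(k_s + k_g)·d`             |
| op_ind | distinct      | distinct        | `L·(k_s + k_g)·d`           |

Because the input dimension is `m` genes but the working width is
`d_emb`, a learned linear encoder `m → d_emb` precedes layer 1 and an
MLP decoder (one hidden ReLU layer of width `d_emb`) maps back to gene
space; `raw_features=True` instead runs the literal `f⁰ = X_obs` with
width `m`. Single-modality variants (`var_s`, `var_g`) duplicate the
active branch's convolution into both halves of the concatenation, so
parameter shapes are unchanged across the ablation.

Initialisation: operators near `1/k` (uniform ±10%) so the initial
convolution approximates a path mean; linear maps Glorot-uniform. The
decoder's output bias is warm-started at the per-gene mean of the
*training* entries, with the output weights shrunk 10×, so the model
starts at the column-mean predictor and optimisation works on the
graph-derived residual structure. Without this, most of the epoch
budget is spent re-learning per-gene offsets through a zero bias. The
warm start touches no held-out value and is applied identically to the
path model and the GCN baseline in every comparison.

Defaults (recommended settings): `L = 4`, `d_emb = 64`,
`k_s = k_g = 8`, `T_s = T_g = 8`, `q_s = q_g = 1`, `p = 1`,
`share_mode = op_ind`. `p` is exposed but defaults to 1. The gene-graph
neighbour count and the gene-path length are independent settings
(`graph.gene_knn` vs `model.k_g`).

Gradients are hand-derived reverse-mode (the network is a short chain
of gathers, channel-wise products, affine maps and ReLUs), verified
against central finite differences to 1e-4 relative in the test suite.
Optimiser: Adam, `lr = 1e-3`, weight decay `1e-5` (biases excluded),
full batch — at ≤ 5k cells there is no need for mini-batching.
Early stopping: patience 50 epochs on validation RMSE, best weights
restored; final test metrics use walks from a reserved evaluation
stream. All arithmetic is float64; runs are bit-reproducible
single-threaded given one seed.

## Synthetic data generator

The generator emulates the regime of real spatial panels (observed
density ~0.2–0.3 after filtering) and the two structures the model
exploits:

* cells on a hexagonal lattice (pitch 1, so distance thresholds in
  fixtures are interpretable) split into `n_layers` contiguous
  horizontal bands;
* per-band expression programs (each band activates one latent factor
  with Gaussian gene loadings) — the cell-type-specific signal;
* a smooth field summing three low-frequency plane waves with gene-wise
  amplitude and phase — the spatial-gradient signal;
* log-rate = base + type + field + Gaussian noise, pushed through
  softplus to a Poisson rate; counts drawn, then independent Bernoulli
  dropout (default rate 0.45, giving ~27% observed density; the
  expected density has a closed form used as a test oracle).

Named fixtures: `tiny` (30×20, unit tests), `layered` (500×200, both
signals — the benchmark fixture), `smooth_only` (no type programs),
`type_only` (no smooth field and coordinates scrambled, so the spatial
graph is uninformative while expression marginals are untouched).

What passing on this generator does **not** show: it has no spot
mixing, no segmentation artifacts, no batch effects, no
platform-specific count distributions (a negative-binomial option is a
possible extension), and its gene-gene correlation structure is
low-rank by construction. Results on it demonstrate the machinery and
the qualitative trends, not real-data accuracy levels.

## Desk-scale experiment protocol

The scripted studies (receptive-field sweep vs GCN, modality ablation,
operator-sharing ablation) run on the layered fixture with a reduced
configuration chosen so a full multi-seed study completes in minutes on
one CPU core: `L = 2`, `d_emb = 32`, `k = T = 4`, Adam `lr = 5e-3`,
max 150 epochs, patience 20, 5 mask seeds, identical masks, graphs and
seeds across the arms of any one comparison (fingerprint-checked). The
receptive field of the path model is mapped as `R = (k − 1)·L` with `L`
fixed and `k` varied; the GCN's is its depth. The GCN baseline is
minimal by design — symmetric-normalised averaging over the union of
both edge sets with a linear map and ReLU per layer, same encoder/
decoder, loss, warm start and early stopping as the path model — an
over-smoothing anchor, not a tuned competitor.

## Known limitations

* The operator-sharing comparison is nearly flat at desk scale: all
  four modes land within ~0.002 RMSE of each other on the layered
  fixture (channel-distinct is directionally better). The synthetic
  task's residual structure is too simple to make channel-shared
  operators a binding constraint, so the large qualitative gaps seen on
  real tissue do not reproduce here.
* Single-sample only: no batch integration, no image modality, no spot
  deconvolution, no inference on cells outside the training graph.
* Exact kNN and dense pairwise distances bound practical size to
  ~10⁴ cells; no approximate-NN backend is wired in.
* The spatial graph follows the distance-threshold definition; spatial
  kNN can be emulated by choosing `d_thr` but is not a separate mode.
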