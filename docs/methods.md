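# Methods

## Model

### Directed message passing

A molecule parsed from SMILES becomes a directed graph in which every
chemical bond contributes a pair of opposite edges with identical bond
features. The bond state of edge v→w is initialized from the source
atom's features concatenated with the bond features,
h⁰_vw = ReLU(W_i [x_v ; e_vw]), and updated for T iterations by
aggregating the states of edges arriving at v while subtracting the
reverse edge w→v, h^t_vw = ReLU(h⁰_vw + W_h m^t_vw) with
m^t_vw = Σ_{k∈N(v)} h^{t−1}_kv − h^{t−1}_wv. The update re-injects the
*initial* state h⁰ additively at every step (not the previous state),
so a terminal atom's outgoing edge — whose only incoming message is its
own reverse, which cancels — is a fixed point of the iteration. Atoms
with no neighbors use the zero vector for the empty sum.

### Attention readout

Per-atom messages m_v = ReLU(W_0 [x_v ; Σ_w h^T_vw]) form the rows of a
matrix on which multi-head scaled dot-product self-attention operates.
Each head computes softmax(QKᵀ/√d_head)V with per-head query/key/value
maps; the scaling uses the per-head width d_head = d/heads (the standard
multi-head convention — with shared-parameter heads this differs from
scaling by √d only by a constant absorbable into W_Q/W_K). Head outputs
are concatenated, combined by W_o, and the residual m_v is added after
that combination. The molecule vector is the plain sum Σ_v h_v, which
together with per-molecule attention makes the encoding exactly
invariant to atom reordering. In batched encoding, molecules form a
disjoint union for the message-passing phase, and attention runs on each
molecule's own atom block, so no attention crosses molecule boundaries
and no padding enters any softmax. No layer normalization is used inside
the attention block; regularization is dropout only (applied to atom
messages and FFN hidden layers during training), keeping the readout a
pure attention-plus-residual map.

### Classifier head

The molecule vector, optionally concatenated with a Morgan/ECFP bit
vector (default radius 2, 2048 bits; both configurable), feeds a
feed-forward network with ReLU hidden layers — `ffn_layers` counts
linear layers, so the default 2 is one hidden layer plus the output —
trained with binary cross-entropy on logits (the numerically stable
formulation). The decision threshold is fixed at 0.5.

## Featurization schema

The one-hot blocks follow the common directed-MPNN convention and are
defined once in `aampnn.featurization` (`ATOM_FEATURE_BLOCKS`,
`BOND_FEATURE_BLOCKS`): atomic number 1–100 with an unknown bucket,
degree 0–5, formal charge −2…+2, four chirality tags, H count 0–4,
five hybridizations (each with an unknown bucket except chirality,
whose "other" tag is its own catch-all); bond type
single/double/triple/aromatic, in-ring yes/no, six stereo categories.
Hydrogens are implicit and enter only through the H-count block;
charged species are kept as parsed; missing stereo annotations fall in
the "none"/"unspecified" categories. Every atom row carries one extra
trailing **mask-slot** column, zero for real atoms — the contrastive
mask token is the all-zeros row with this slot set to one, which makes
it distinct from every valid encoding by construction.

## Contrastive pretraining

Positive pairs are (original graph, atom-masked graph) by default; a
dual-masked-views option exists but is off. Masking replaces
max(1, floor(0.25·M)) uniformly chosen atoms with the mask token; bond
features are untouched. Projections go through a two-layer MLP head
(widths configurable), and the NT-Xent loss is computed **exactly in
the stated form**: the denominator for anchor i sums, over j = 1…N,
the cross-view terms e^{sim(z_i,z_j′)/τ} and e^{sim(z_i′,z_j)/τ} — the
positive pair is included and there are no within-view negatives. This
differs from the common SimCLR form (which excludes the positive from
the denominator and adds within-view negatives); the consequences are
the analytic limits used in tests: at N = 1 the loss is exactly log 2
and with all-identical embeddings at N = 2 it is log 4. τ defaults to
0.1. The corpus is split 90:10 into train/validation under the config
seed; incomplete trailing batches are dropped (contrastive losses are
batch-size sensitive) unless no full batch exists, in which case the
whole set forms one batch. Only the encoder parameters are returned;
the projection head is discarded. Pretraining epochs and optimizer
(Adam, 1e-3) are exposed as configuration with these defaults.

## Supervised protocol

Datasets are split by stratified random sampling into 70% calibration
(training), 15% validation and 15% test — read as fractions of the full
dataset, consistent with an 85:15 train/test division whose training
side is itself split 70:15. Scaffold-holdout splitting (whole Murcko
scaffolds held out of training) is available as an option for
generalization analysis. Stratified five-fold cross-validation reports
mean and sample standard deviation (ddof = 1) of ROC-AUC, accuracy,
precision, sensitivity and specificity. When a pretrained encoder is
supplied, it initializes the encoder and is fully fine-tuned by
default; a freeze flag restricts training to the head.

Hyperparameter search runs a tree-structured Parzen estimator over the
fixed grid — message iterations {2…6}, batch size {128, 256, 512},
dropout 0–0.4 in 0.05 steps, FFN layers {2, 3}, log-uniform learning
rate [1e-4, 1e-3] — scoring each trial by validation ROC-AUC. The TPE
splits past trials at the top quartile, samples candidates from the
good-trial densities (categorical counts with a +1 prior; log-space
Gaussian kernels for the rate) and picks the best good/bad density
ratio, with 8 random start-up trials and a 20% exploration rate.

## Numerical core

The networks run on a small in-repo reverse-mode autodiff engine over
NumPy arrays (`aampnn.tensor`): dense matmul, elementwise
nonlinearities, reductions, concatenation, row gathering and segment
sums, each with a hand-written vector-Jacobian product verified against
central finite differences in the test suite. Optimization is Adam with
bias-corrected moments. All computation is float64 and single-threaded
NumPy, which makes runs bit-reproducible for a fixed seed; every
stochastic component (initialization, batching, masking, dropout,
splits, TPE) draws from PCG64 generators seeded explicitly.

## Curation

Records carrying log10 apparent permeability (cm·s⁻¹) are standardized
— largest organic fragment kept (salt/solvent stripping), charges
neutralized — then filtered to the reliability window
−8 ≤ log Papp ≤ −3.5. Two-cluster k-means (10 restarts, fixed seed) on
the retained one-dimensional values induces a monotone labeling; the
reported threshold is the midpoint between the maximum of the lower
cluster and the minimum of the upper cluster, and the
higher-permeability cluster is labeled permeable. On a bimodal sample
with modes at −6.5/−4.5 the derived threshold lands near −5.5, matching
the empirical low/high permeability cuts used in the field. Binary
labeled datasets (e.g. BBB) are ingested as plain CSV; no further
label computation applies. Full replication of the ChEMBL
standardization pipeline is out of scope; the applied steps are exactly
the two above.

## Synthetic data

The fixture generator assembles molecules from a curated fragment
grammar: ring scaffolds (half containing an aromatic nitrogen, half
not), small aliphatic substituents attached at random C–H sites, and an
occasional second ring. It emulates a drug-like classification corpus
with a plantable structure–label signal — label = presence of a
configurable substructure (default aromatic nitrogen, SMARTS `[n]`)
with optional label noise — and a permeability corpus in which log Papp
is drawn from a two-component Gaussian mixture (default modes −6.5 and
−4.5, σ = 0.3) tied to the same substructure. Defaults for the study
tasks: 500 molecules for supervised learning, 200 for pretraining, 400
for curation — sizes at which the pipeline exercises every code path
while training remains a desk-scale computation. What the generator
does **not** emulate: the scaffold diversity, class imbalance, activity
cliffs and assay noise of real permeability datasets — passing the
synthetic studies demonstrates correctness of the machinery and
learnability of a planted signal, not real-data predictive performance.

## Interpretation choices

Attention weights are nonnegative and rows sum to one, so they cannot
by themselves assign a direction of effect. Per-atom aggregated weight
is defined as the mean over heads of the attention an atom receives
(column means of the row-stochastic matrices; max aggregation via
flag), renormalized to sum to one. The signed contribution is defined
by single-atom occlusion: probability(original) − probability(atom
replaced by the mask token), computed with the molecule's original ECFP
held fixed so only the graph channel is perturbed. This occlusion
definition is this package's own interpretation device for coloring
atoms green (positive) or red (negative) with intensity ∝ |contribution|.
Depictions are SVG (PNG requires the optional Cairo drawing backend);
a per-atom CSV table accompanies every depiction. Embedding maps reduce
molecule vectors to 2-D with t-SNE (perplexity auto-capped below the
molecule count).

## Known limitations

- CPU-only float64 NumPy: fine for desk-scale studies (hundreds to a
  few thousand molecules, hidden widths up to a few hundred), not for
  corpus-scale pretraining.
- The NT-Xent form is implemented as stated, not the SimCLR variant;
  loss values are not directly comparable to SimCLR implementations.
- Occlusion contributions are a model-interrogation heuristic; they
  inherit any biases of the trained model.
- Probability calibration, regression targets and multi-task heads are
  out of scope.
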