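# Methods

## Model

A molecule is represented as a typed, directed multigraph at three
granularities (molecule / element / drug views). Both nodes and directed
edges carry embeddings; the two directions of a chemical relation are
distinct states because each edge's initial embedding absorbs its *source*
node's initial embedding:

    h⁰_v  = α A_δ(v) + a₀ + λ C₀ + c₀
    h⁰_eij = β B_δ(e) + b₀ + h⁰_vi

with per-type input projections A_δ, B_δ (feature widths may differ per
type), and a learned map of the positional vector λ.

Each of L layers performs synchronous dual message passing with K-head
attention, scale √(d/K): queries come from the receiver, keys/values from
the senders. A node's senders are exactly its incoming directed edges; an
edge e_ij's senders are its source node v_i plus the edges entering v_i
(which include the reverse edge e_ji). After the shared per-head
projections W_Q/W_K/W_V, a per-type square transform W_δ (one per node
type and one per edge type, shared across layers, heads, and the Q/K/V
roles) maps heterogeneous types into one comparison space. Head outputs
are concatenated and mixed by W^V (nodes) / W^E (edges); updates are
h^l = LeakyReLU([h^{l−1} ‖ m^l] W^l_δ) with the receiver's type-specific
W, applied to all nodes and all directed edges from the *previous* layer's
state (no receiver sees a same-layer update). Isolated receivers (empty
sender set) get a zero message.

Readout is self-attention graph pooling over the union of final node and
directed-edge embeddings: a shared linear-plus-tanh scorer, retention of
the top ⌈r·(|V|+|E_directed|)⌉ units (r = 0.5), and an output
h_G = Σ a_i s_i h_i with a = softmax over retained scores. The retained
attention weights sum to 1 and are exported per node type (normalized
within type) for inspection of what the encoder attends to.

## Contrastive objective

Projected embeddings z = f_projector(h_G) (2-layer MLP, tanh, rows
unit-normalized, so sim = cosine) feed an InfoNCE loss with temperature
τ = 0.1. For views of sizes M ≤ N aligned on the trailing overlap, the
directed anchor loss uses the positive pair in the numerator and, in the
denominator, the anchor view's other rows plus the partner view's
non-positive rows — (M−1) + (N−1) = N+M−2 negative terms; the positive is
not in the denominator, and the directed loss is asymmetric in its views.
The per-pair loss ℒ1,2 averages both directions over the min(M, N)
anchors; the total is ℒM,EM + ℒM,DM + ℒEM,DM. Degenerate pairs (an empty
drug view) contribute 0 with a warning. Logits are shifted by the maximum
before exponentiation.

## Batch generation

Non-drug molecules are clustered by equal-size K-means (size ⌈0.7N⌉) on
Morgan fingerprints (radius 2, 1024 bits, Euclidean distance — the
clustering feature space is this package's choice; a centroid metric is
required). Size constraints are enforced exactly per iteration by solving
a minimum-cost point-to-slot matching (`linear_sum_assignment`) against
seeded K-means initial centroids, alternating with centroid updates.
Leftover molecules short of a full cluster are dropped and logged. Each
cluster then receives the ⌈0.3N⌉−n unused drug molecules nearest its
centroid (accumulated into the used set 𝒮U, so nearest-neighbour
complements are globally disjoint, consumed in ascending cluster order)
and finally n drug molecules sampled uniformly from the pool outside 𝒮U —
random fills are *not* added to 𝒮U, so they may recur across batches but
never within one. Rounding: 0.7N → ⌈0.7N⌉ non-drug and N − ⌈0.7N⌉ drug
slots, so batches are integral and sum to N. Drug records occupy the
trailing positions, which is the row alignment the contrastive loss
assumes.

## Fine-tuning

The projector is discarded. The pooling scorer is re-initialized per task;
message-passing weights are kept. A 2-layer MLP head maps h_G (property
prediction) or the ordered concatenation [h_G1, h_G2] (DDI prediction,
both graphs encoded by the same encoder) to the target; regression uses
MSE, binary/multilabel tasks use sigmoid cross-entropy on logits. Head
inputs are standardized feature-wise with moments fixed from the initial
embedding pass — pooled embeddings are small in scale and the fixed affine
correction conditions the head fit without leaking label information.
Frozen-encoder mode (default) trains only the head on cached embeddings;
unfrozen mode backpropagates through the encoder. Optimizer is Adam,
lr 1e-3 (pre-training) / 1e-2 (head fitting) by default.

## Synthetic data

The element KG is a curated three-level chemistry KG: class nodes
(Nonmetals, ReactiveNonmetal, Halogens), chemical-level nodes (H, C, N, O,
F, S, Cl, Br, P with real periods and atomic-weight buckets; ~11
functional groups with literature SMARTS, e.g. Acetal `O[CH1][OX2H0]`),
and property nodes (Period*, Weight*). The triple inventory is curated —
only per-entity attribute vectors (unit-norm, width 8) are seeded — so the
AE/FrFu attachment and 2-hop edge semantics operate on real chemistry and
triple lists are identical across seeds. The drug KG links seeded drug
entities to genes/diseases/side-effects etc. and assigns unit-norm random
embeddings as a stand-in for trained KG embeddings; an external embedding
table can be supplied. Molecule pools draw from ~20 in-code SMILES
templates chosen to cover aromatic rings, halogens, esters, amides,
nitriles, ethers and acids, so BRICS cleaves some molecules and not
others; a configurable minority fraction of records receives drug ids.

What the generator does *not* emulate: realistic molecular size and
scaffold diversity (templates are small, ≤ 13 heavy atoms), trained KG
embedding geometry (random embeddings carry no pharmacology), KG scale
(dozens of entities, not thousands), or label noise. Passing tests
demonstrate the correctness of the graph construction, encoder algebra,
loss accounting and batching logic — not predictive performance on real
chemistry.

## Numerical and design choices

* **Feature schema** (the standard molecular-GNN one-hots): atom = element
  one-hot (+other) ‖ degree 0–5 ‖ formal charge −2..2 ‖ aromatic ‖
  hybridization ‖ ring bit (28 dims); bond = order one-hot ‖ conjugation ‖
  ring (6); fragment = mean of member atoms ‖ heavy-atom count; reaction =
  one-hot pair of BRICS rule labels; join = constant 1; AE/FrFu/AD/FrD =
  relation one-hot; EE/FuFu/EFu = intermediate attribute vector ‖ KG
  relation one-hot (one half zeroed depending on 1-hop vs 2-hop origin).
  Hydrogens are implicit.
* **Positions**: λ = 8 lowest Laplacian eigenvectors of the atom–bond
  subgraph, zero-padded, sign-fixed (first nonzero component positive);
  fragment/KG/drug nodes get λ = 0.
* **Functional-group matching** runs SMARTS search on the intact molecule
  and attributes each match to every fragment it touches. Per-fragment
  submol matching was rejected for two reasons: RDKit aromaticity is
  ill-defined on excised fragments, and BRICS frequently cleaves *through*
  functional groups (the ester bond itself), which would make the groups
  that motivate fragmentation undetectable.
* **Pooling ties** are broken by score, then a relabeling-invariant key
  (unit kind, type, rounded embedding), so the readout is stable under
  node reordering up to float association (~1e-6).
* **Attention scale** is √(d/K), the per-head width. Empty softmax rows
  (no senders) yield zero messages via a mask-derived denominator guard.
* **Parameter init**: per-matrix uniform(±1/√fan_in), seeded; LeakyReLU
  slope 0.01.
* **Checkpoints** are a single JSON archive (named arrays + header with
  d/K/L/r and a feature-schema hash) — diffable and text-only.
* **Problem sizes**: tests and the acceptance script run d = 16, K = 2,
  L = 2, batches of N = 10 over pools of 30–100 template molecules, 50
  pre-training steps, 200 fine-tuning epochs — sizes at which every
  quantity is recomputable in seconds to minutes on one CPU while
  exercising all code paths.

## Known limitations

* The whole stack is CPU NumPy with a minimal tape-based autodiff;
  it is intended for desk-scale experiments, not large corpora.
* Property/class KG entities enter the HMG only through 2-hop edge
  features, never as nodes.
* Constrained K-means solves the assignment step exactly but the overall
  clustering is still a heuristic alternation, seeded for determinism.
* No 3D conformers, stereochemistry, or tautomer handling; SMILES-level
  input only.
* Fine-tuning metrics reported by the tests are training-set fits
  (learnability checks), not generalization estimates.
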