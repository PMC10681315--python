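# Methods

## Network construction

A drug table (id → SMILES) is decomposed with BRICS retrosynthetic rules.
One decomposition step is a *single pass*: every cleavable bond of the
molecule is cut once, in isolation, and both halves are emitted; recursing
on the children until no BRICS bond remains yields the full fragment
lattice, intermediate (still divisible) fragments included.  This choice —
rather than cutting all bonds simultaneously — is what gives the
fragment→fragment network Z its content: Z records "child is a cleavage
product of parent", and the quadrilateral motifs (A₃, A₆) read drug pairs
whose fragments stand in that relation.  Attachment dummy atoms keep a
bond-type label after cleavage; all labels are collapsed to a generic `*`
before canonicalization so the same functional group reached through
different cleavage contexts is one node.  Drug→fragment edges point only
to first-level fragments; deeper containment is carried transitively by Z.
Fragments are numbered in sorted-canonical-SMILES order, making outputs
byte-reproducible.

Typed edge lists populate binary matrices S (drug–drug, symmetrized, zero
diagonal), W/G/V (drug–target / side-effect / disease) over registries
that map string ids to dense indices in first-seen order.

## Motif hypergraphs

The twelve motif count matrices follow the closed algebraic forms over
{S, Y, Z, W, G, V} with the diagonal zeroed afterwards (the printed
products leave degrees on the diagonal, but a motif needs two *distinct*
anchor drugs).  Y and Z stay directed; only the quadrilateral form
Aₘ = YZYᵀ is explicitly symmetrized as Aₘ + Aₘᵀ.  Drug-independent counts
contain their drug-related counterparts as the S-masked subset, so the
subtraction A₄−A₁ … A₁₂−A₉ is exact and non-negative by construction; a
negative entry is asserted as an internal error, never clamped.  All
arithmetic in this stage is integer.

A motif whose inputs are absent (e.g. no side networks) is skipped; a
branch with no available motif is disabled and the encoder renormalizes
its attention over the remaining branches.  When S is absent there are no
drug-related instances to subtract, so the independent counts pass through
unsubtracted.  Per cross-validation fold, the incidences are rebuilt from
the training view only — the fold's test edges exist nowhere in the
matrices the model sees.

A brute-force enumerator (explicit loops over anchor pairs and middle
nodes, checking edges one at a time) provides the independent oracle; the
test suite requires exact integer equality on dozens of random
heterogeneous networks.

## Encoder

Defaults: embedding dimension c = 100, depth L = 2.  Per branch, the
shared drug table D₀ is self-gated (X ⊙ σ(XP + B)), propagated through L
hypergraph-attention layers

    D' = rowsoftmax(Iˣ D_l D_lᵀ) D_l,
    D_{l+1} = D⁻¹ relu(D' P + B),

and layer-averaged.  Numerical conventions: softmax with max-subtraction;
degree pseudo-inverse 1/0 := 0, so an isolated drug contributes no
hypergraph signal but still receives convolution signal; float64
throughout (the graphs are desk-scale, so the precision costs nothing and
lets oracle tests run at 1e-8).  The softmax row spans all b columns of
the dense score matrix, faithful to the printed operator; a masked variant
restricted to the incidence's nonzeros is available behind
`masked_softmax` (default off).  Branch propagation blocks are shared
across layers; `propagation_params: off` freezes all propagation blocks at
identity/zero, leaving exactly the nine gates, two embedding tables and
the attention parameters trainable.  Per-drug branch weights ω are
computed once from the layer-averaged branch embeddings and reused at
every layer of the fusion; the fusion term is implemented exactly as
Σₓ ωˣ D_lˣ + ½ D_l^c (not a two-term average).  The entity table M₀
enters the convolution ungated, as only the drug table has a gate in the
model definition.

Initialization: embeddings uniform(−0.05, 0.05)/√c, weight matrices
Xavier-uniform, biases zero, all from one seeded generator.

## Objective and training

BPR samples, per epoch, one triple (d, i, j) per observed training edge
(with replacement; j uniform over d's unobserved entities; drugs with
fully observed rows are skipped with a warning), minibatched at 2000.
The L2 penalty (δ = 0.01) covers every trainable block.  The
self-supervised term gates the *final* drug table per branch, reads out
drug-centred sub-hypergraph summaries s_d = (Iˣ[d]·Dˣ)/#nonzeros — the
incidence weights are kept, the divisor counts members — averages the
valid summaries into a graph vector g, corrupts the summary table by one
row and one column permutation, and scores agreement with a parameter-free
inner-product discriminator at both hierarchy levels.  Drugs with empty
hyperedge rows are excluded from the loss.  λ = 0.001 by default; the
total objective is L_s + λ·L_self, optimized by Adam at 0.001 ("adaptive
learning rate", no schedule), up to 200 epochs, no early stopping.

Gradients come from a small reverse-mode tape over numpy
(`hyperdrug.autodiff`) written for this model — broadcasting arithmetic,
matmul, sigmoid/relu/softplus, stable row softmax, reductions, gathers,
permutations.  Every primitive and the full objective are checked against
central finite differences; the full-model check compares per-block
gradient norms at a parameter point of magnitude ~0.1, because at the
near-zero default initialization some relu pre-activations fall inside
the finite-difference window and the *numeric* side of the comparison
breaks down at the kink.

Ablation switches: `no_hyper` (no branches), `frag_only` (substructure
branches j, p), `mol_only` (interaction branches i, u), `conv` (attention
replaced by degree-normalized incidence propagation), `no_ssl` (λ = 0).

## Evaluation

Folds partition positive edges at the edge level; each fold carries fixed
1:1 negatives sampled uniformly from non-edges, never overlapping any
known positive and never reused across folds — fixed, rather than
resampled per epoch, so metrics are comparable across models and epochs.
AUROC is the tie-corrected rank statistic and AUPR the step-integrated
average precision (no linear interpolation), both via scikit-learn and
verified against O(n²) pair counting.  Novel-interaction ranking scores
all unobserved pairs with deterministic tie-breaking (score desc, drug
id, entity id); drug similarity is cosine over embeddings with zero rows
flagged as having no defined neighbor.

## Synthetic benchmark and its information ceiling

The planted-partition generator (defaults b = 60 drugs, t = 40 entities,
2 blocks, p_in = 0.25, p_out = 0.02, 6 fragments per block, 1 noise
fragment per drug) aligns fragment pools, the drug–drug network and the
task matrix with the same latent blocks, with repairs guaranteeing every
drug at least one fragment and one edge.  Each block pool carries an
anchor fragment present in every member drug, so with zero noise the
shared-fragment counts are strictly positive within blocks and zero
across.

Because held-out edges are conditionally independent Bernoulli draws
given the blocks, and every observable (S, Y, Z, training R) is a
function of block membership, the Bayes-optimal test score is a function
of the block pair alone.  Its AUROC — counting tied comparisons one
half — is

    AUROC* = q₊(1−q₋) + ½[q₊q₋ + (1−q₊)(1−q₋)] ≈ 0.746,

with q₊ = 300/324 the fraction of positives within blocks and
q₋ = 900/2076 the within-block fraction of uniform non-edge negatives.
The trained model reaches ≈ 0.73–0.74 (untrained ≈ 0.5), i.e. it
recovers essentially all recoverable structure; numbers above the
ceiling are impossible on this generator by design, not by model limits.
Raising p_in (toward the deterministic p_in = 1, p_out = 0 corner)
raises the ceiling toward 1.  The generator reproduces none of the heavy-
tailed degree structure, biases or noise of curated interaction
databases, so results here demonstrate mechanism recovery, not expected
field performance.

Training-scale choices for the shipped benchmark runs: c = 32 and 100
epochs, which converge on this problem size in seconds per fold.

## Known limitations

- Dense integer matrices cap practical network size at a few thousand
  drugs; the motif algebra itself is sparse-friendly if ever needed.
- The single-pass/recursive fragment lattice can grow quadratically in
  the number of cleavable bonds for large flexible molecules.
- The attention softmax over all b columns makes each branch layer
  O(b²c); the masked variant trades fidelity to the printed operator for
  sparsity.
- Loaders for public interaction databases are out of scope; only local
  edge-list ingestion is provided.
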