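# hyperdrug

Motif-driven hypergraph attention networks for predicting drug-related
interactions — drug–drug (DDI), drug–target (DTI), drug–disease (DDiI)
and drug–side-effect (DSI) links — from a drug-centric heterogeneous
network that couples interaction data with drug substructure.

## Who this is for

Computational drug-discovery groups who have (a) a table of drugs with
SMILES and (b) one or more typed interaction edge lists, and want a link
predictor that exploits *high-order* drug relatedness — "these two drugs
close the same triangle", "these two drugs contain the same functional
group" — rather than pairwise edges alone.

## The model

**Network.** Each drug's SMILES is cleaved recursively at BRICS
(retrosynthetic) bonds down to indivisible functional-group fragments,
giving directed drug→fragment (Y) and fragment→fragment (Z) networks.
Together with the drug–drug matrix S and the task matrix
R ∈ {S, W, G, V}, these form one heterogeneous network.

**Hypergraphs.** Twelve small motifs (triangles and quadrilaterals
anchored on two drugs) are counted in closed matrix form, e.g.
A₁ = (SS)⊙S (drugs linked *and* sharing an interacting partner),
A₅ = YYᵀ (drugs sharing a fragment), A₆ = YZYᵀ + (YZYᵀ)ᵀ (fragments of
one drug that are cleavage products of the other's).  The motifs split
into four groups by two semantics — anchors directly linked or not ×
evidence from substructure or from molecular interactions — and
drug-independent counts have their drug-related subset subtracted
(A₄−A₁, …).  Each group sums to a drug×drug incidence matrix
I_j, I_p, I_i, I_u whose row d is a drug-d-centred hyperedge.

**Encoder.**  Per branch x: a self-gate D₀ˣ = D₀ ⊙ σ(D₀P + B), then L
layers of hypergraph attention

    D_{l+1} = D⁻¹ relu( rowsoftmax(Iˣ D_l D_lᵀ) D_l · P + B ),

layer-averaged to avoid over-smoothing.  Per-drug attention weights ωˣ
fuse the branches, and a bipartite graph convolution on R mixes in
drug-related entity embeddings M.  Scores are inner products ŝ_{d,i} =
D_d·M_i.

**Objective.**  Bayesian Personalized Ranking over sampled (drug,
observed, unobserved) triples plus an L2 penalty, and a Deep-Graph-
Infomax-style self-supervised term that maximizes agreement between
drug, sub-hypergraph and whole-hypergraph summaries against shuffled
negatives: L = L_s + λ·L_self, trained with Adam.

Everything differentiable runs on a small reverse-mode autodiff tape
over numpy (`hyperdrug.autodiff`), validated end-to-end against finite
differences.

## Worked example

Fit on a synthetic planted-partition benchmark (60 drugs, 40 entities,
two latent blocks; fragments aligned with blocks so the substructure
hypergraphs carry real signal):

```python
from hyperdrug import (PlantedNetworkSpec, make_planted_network,
                       DrugLinkModel, TrainConfig, cross_validate, rank_novel)

hetero, task = make_planted_network(PlantedNetworkSpec(seed=7))
model = DrugLinkModel(task, hetero, TrainConfig(dim=32, epochs=100, seed=7))
cv = cross_validate(model, k=5, seed=7)
print(f"mean AUROC {cv.mean_auroc:.3f} +/- {cv.sd_auroc:.3f}")
print(f"mean AUPR  {cv.mean_aupr:.3f} +/- {cv.sd_aupr:.3f}")
print(model.fit().summary())
```

prints

```
mean AUROC 0.742 +/- 0.063
mean AUPR  0.689 +/- 0.063
Drug link prediction model
==========================================================
Task:               DTI (60 drugs x 40 entities)
Positive edges:     317
Enabled branches:   j, p, i, u
Embedding dim:      32
Layers:             2
Ablation:           full
Epochs run:         100
Loss (first epoch): 225.2259 (BPR 224.8946, SSL 331.3233)
Loss (last epoch):  169.2334 (BPR 168.9250, SSL 308.4425)
Mean branch attention: j=0.250, p=0.250, i=0.251, u=0.250
==========================================================
```

The cross-validated AUROC of 0.74 sits essentially at this generator's
information ceiling: held-out edges are Bernoulli given the two blocks,
so the best possible (block-oracle) AUROC is ≈ 0.746 — see
`docs/methods.md`.  An untrained encoder scores ≈ 0.5.  `rank_novel`
then lists the top unobserved candidate pairs, and `drug_similarity`
gives cosine similarities between learned drug embeddings.

The same pipeline is scriptable from the shell:

```bash
hyperdrug simulate --out sim --drugs 60 --entities 40 --seed 7
hyperdrug evaluate --task DTI --edges sim/task_edges.tsv \
    --side DDI=sim/ddi_edges.tsv --dim 32 --epochs 100 --seed 7 --out eval
hyperdrug decompose drugs.tsv --out fragments   # real SMILES tables
```

Ablations (`--ablation no_hyper|frag_only|mol_only|conv|no_ssl`) switch
off the hypergraph branches, keep only the substructure or only the
molecular-interaction branches, replace attention by plain hypergraph
convolution, or drop the self-supervised term.

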