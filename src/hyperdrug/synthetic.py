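"""Synthetic desk-scale inputs with the signal structure the model exploits.

Two generators:

* :func:`make_toy_smiles` emits valid SMILES assembled from scaffold +
  substituent templates joined through ester/amide linkages that BRICS
  cleaves, so drugs built on the same scaffold share fragments — the
  premise that drugs with a common substructure behave alike, made
  literal.

* :func:`make_planted_network` draws a planted-partition task network:
  drugs and entities fall into blocks, interactions are Bernoulli(p_in)
  within a block and Bernoulli(p_out) across, the drug-drug network S
  follows the same partition, and the drug-fragment matrix Y gives every
  block its own fragment pool (plus uniform noise fragments).  Fragment
  signal is aligned with link structure by construction, so shared-
  fragment motifs are informative for held-out links and recovery is a
  meaningful end-to-end test.  Degree distributions are homogeneous —
  nothing like the heavy tails of curated interaction databases — so
  passing here demonstrates mechanism, not field performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import HeteroNetwork, Registry, TaskNetwork

__all__ = ["PlantedNetworkSpec", "make_toy_smiles", "make_planted_network"]

# scaffold templates with two open positions, and substituents; joined as
# sub1-C(=O)O-scaffold-OC(=O)-sub2 style esters that BRICS rule 1/3 cleaves
_SCAFFOLDS = [
    "c1ccc({0})cc1{1}",            # benzene
    "c1ccnc({0})c1{1}",            # pyridine
    "C1CCC({0})CC1{1}",            # cyclohexane
    "c1ccc2cc({0})c({1})cc2c1",    # naphthalene
    "c1occ({0})c1{1}",             # furan
    "C1CCN({0})CC1{1}",            # piperidine
]
_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "CCO", "CCN"]
_LINKERS = ["OC(=O){s}", "NC(=O){s}", "COC(=O){s}"]


def make_toy_smiles(n_scaffolds: int, per_scaffold: int,
                    seed: int = 0) -> list[tuple[str, str]]:
    """Deterministic (drug_id, smiles) table; same-scaffold drugs share
    their core fragment after BRICS decomposition."""
    from rdkit import Chem

    if n_scaffolds > len(_SCAFFOLDS):
        raise ValueError(f"at most {len(_SCAFFOLDS)} scaffolds available")
    rng = np.random.default_rng(seed)
    table = []
    for s in range(n_scaffolds):
        scaffold = _SCAFFOLDS[s]
        combos = [(li, su) for li in _LINKERS for su in _SUBSTITUENTS]
        picks = rng.choice(len(combos), size=per_scaffold, replace=False)
        for n, pick in enumerate(picks):
            linker, sub = combos[pick]
            arm1 = linker.format(s=sub)
            arm2 = _LINKERS[0].format(s=_SUBSTITUENTS[(s + n) % len(_SUBSTITUENTS)])
            smiles = scaffold.format(arm1, arm2)
            mol = Chem.MolFromSmiles(smiles)
            assert mol is not None, f"template produced invalid SMILES {smiles}"
            table.append((f"D{s:02d}_{n:02d}", Chem.MolToSmiles(mol)))
    return table


@dataclass
class PlantedNetworkSpec:
    b: int = 60               # number of drugs
    t: int = 40               # number of task entities
    n_blocks: int = 2
    p_in: float = 0.25        # within-block interaction probability
    p_out: float = 0.02       # between-block interaction probability
    frags_per_block: int = 6
    frag_noise: int = 1       # off-pool fragments per drug
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.b % self.n_blocks or self.t % self.n_blocks:
            raise ValueError("b and t must be divisible by n_blocks")


def make_planted_network(spec: PlantedNetworkSpec
                         ) -> tuple[HeteroNetwork, TaskNetwork]:
    """Planted-partition heterogeneous network + bipartite task network.

    Guarantees: S symmetric zero-diagonal; every drug has >= 1 fragment
    and >= 1 task edge (repaired with a random within-block edge if the
    Bernoulli draw leaves a row empty); each block's fragment pool holds
    an anchor fragment carried by every drug of the block, so with
    ``frag_noise=0`` shared-fragment counts are strictly positive within
    blocks and zero across.
    """
    rng = np.random.default_rng(spec.seed)
    b, t, nb = spec.b, spec.t, spec.n_blocks
    drug_block = np.repeat(np.arange(nb), b // nb)
    ent_block = np.repeat(np.arange(nb), t // nb)

    def planted(n_rows, n_cols, rblock, cblock, symmetric=False):
        same = rblock[:, None] == cblock[None, :]
        p = np.where(same, spec.p_in, spec.p_out)
        m = (rng.random((n_rows, n_cols)) < p).astype(np.int64)
        if symmetric:
            m = np.triu(m, 1)
            m = m + m.T
        return m

    R = planted(b, t, drug_block, ent_block)
    for d in range(b):  # repair: every drug needs a positive task edge
        if R[d].sum() == 0:
            cand = np.nonzero(ent_block == drug_block[d])[0]
            R[d, rng.choice(cand)] = 1
    S = planted(b, b, drug_block, drug_block, symmetric=True)

    F = nb * spec.frags_per_block
    frag_block = np.repeat(np.arange(nb), spec.frags_per_block)
    Y = np.zeros((b, F), dtype=np.int64)
    for d in range(b):
        pool = np.nonzero(frag_block == drug_block[d])[0]
        Y[d, pool[0]] = 1  # block anchor fragment: guaranteed overlap
        for f in pool[1:]:
            if rng.random() < 0.6:
                Y[d, f] = 1
        if spec.frag_noise:
            others = np.nonzero(frag_block != drug_block[d])[0]
            extra = rng.choice(others, size=min(spec.frag_noise, others.size),
                               replace=False)
            Y[d, extra] = 1
    # shallow per-block fragment tree: anchor is parent of its pool mates
    Z = np.zeros((F, F), dtype=np.int64)
    for blk in range(nb):
        pool = np.nonzero(frag_block == blk)[0]
        for f in pool[1:]:
            Z[pool[0], f] = 1

    drugs = Registry(f"d{i:03d}" for i in range(b))
    fragments = Registry(f"f{i:03d}" for i in range(F))
    entities = Registry(f"e{i:03d}" for i in range(t))
    hetero = HeteroNetwork(drugs=drugs, fragments=fragments, S=S, Y=Y, Z=Z,
                           W=R.copy(), entity_registries={"DTI": entities})
    hetero.validate()
    task = TaskNetwork(kind="DTI", R=R, drugs=drugs, entities=entities)
    return hetero, task
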