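"""Recursive BRICS fragmentation of drug SMILES.

Drugs are cleaved at BRICS (retrosynthetically interesting) bonds into
functional-group fragments, and fragments are cleaved again until no BRICS
bond remains.  One decomposition step is a *single pass*: every cleavable
bond of the molecule is cut once, in isolation, and both halves are
emitted.  Recursing on those children until the leaves are indivisible
reproduces the full BRICS fragment lattice (intermediate, still-divisible
fragments included) and yields a parent-to-child fragment tree.

The result is two directed edge sets: drug -> first-level fragment (DFI)
and parent fragment -> child fragment (FFI).  Attachment dummy atoms keep
a BRICS bond-type label after cleavage; those labels are normalized to a
single generic attachment point before canonicalization so that the same
functional group reached through different cleavage contexts maps to one
fragment node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import BRICS

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "DrugRecord", "FragmentNode", "FragmentationResult",
    "brics_decompose", "canonicalize_fragment", "recursive_decompose",
    "read_drug_table", "write_fragmentation",
]


class FragmentationError(ValueError):
    """Raised on unparseable SMILES input."""


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass(frozen=True)
class FragmentNode:
    fragment_id: int
    canonical_smiles: str
    divisible: bool


@dataclass
class FragmentationResult:
    fragments: list[FragmentNode] = field(default_factory=list)
    dfi_edges: list[tuple[str, int]] = field(default_factory=list)
    ffi_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def smiles_to_id(self) -> dict[str, int]:
        return {f.canonical_smiles: f.fragment_id for f in self.fragments}


def _parse(smiles: str, what: str = "SMILES") -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise FragmentationError(f"empty {what} string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentationError(f"unparseable {what}: {smiles!r}")
    return mol


def canonicalize_fragment(fragment_smiles: str) -> str:
    """Canonical SMILES with all attachment labels collapsed to ``*``.

    BRICS marks each cut with an isotope-labelled dummy atom recording the
    bond environment (``[3*]``, ``[16*]`` ...).  Two fragments that differ
    only in those labels are the same functional group, so every dummy
    atom's isotope is reset to 0 before canonicalization.  The map is
    idempotent: its output contains only generic ``*`` atoms.
    """
    mol = _parse(fragment_smiles, "fragment")
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def brics_decompose(smiles: str) -> list[str]:
    """One single-pass BRICS round: each cleavable bond cut once.

    Returns the canonicalized children (label-normalized, deduplicated,
    sorted).  A molecule with no BRICS-cleavable bond decomposes to itself:
    the returned list is ``[canonical(input)]``.
    """
    mol = _parse(smiles)
    parent = canonicalize_fragment(smiles)
    if not list(BRICS.FindBRICSBonds(mol)):
        return [parent]
    pieces = BRICS.BRICSDecompose(mol, singlePass=True)
    children = {canonicalize_fragment(s) for s in pieces}
    children.discard(parent)
    if not children:  # pragma: no cover - FindBRICSBonds found a bond
        return [parent]
    return sorted(children)


def _is_divisible(canonical: str) -> bool:
    mol = Chem.MolFromSmiles(canonical)
    return mol is not None and bool(list(BRICS.FindBRICSBonds(mol)))


def recursive_decompose(drugs: list[DrugRecord]) -> FragmentationResult:
    """Breadth-first decomposition of a drug table to indivisible leaves.

    DFI edges point from each drug to its first-level fragments; FFI edges
    from each divisible fragment to the children of its own single-pass
    round.  Fragments are merged across drugs by canonical SMILES and
    numbered in sorted-canonical-SMILES order, so output is deterministic.
    """
    bad = []
    for d in drugs:
        if not d.smiles or Chem.MolFromSmiles(d.smiles) is None:
            bad.append(d.drug_id)
    if bad:
        raise FragmentationError(
            "unparseable SMILES for drug ids: " + ", ".join(sorted(bad)))
    seen = set(d.drug_id for d in drugs)
    if len(seen) != len(drugs):
        raise FragmentationError("duplicate drug_id in input table")

    children_of: dict[str, list[str]] = {}
    dfi_raw: list[tuple[str, str]] = []
    queue: list[str] = []
    for d in drugs:
        first = brics_decompose(d.smiles)
        own = canonicalize_fragment(d.smiles)
        if first == [own]:
            dfi_raw.append((d.drug_id, own))
            children_of.setdefault(own, [])
        else:
            for c in first:
                dfi_raw.append((d.drug_id, c))
            queue.extend(first)

    while queue:
        frag = queue.pop()
        if frag in children_of:
            continue
        kids = brics_decompose(frag)
        if kids == [frag]:
            children_of[frag] = []
        else:
            children_of[frag] = kids
            queue.extend(kids)

    ordered = sorted(children_of)
    ids = {smi: i for i, smi in enumerate(ordered)}
    fragments = [
        FragmentNode(ids[smi], smi, divisible=bool(children_of[smi]))
        for smi in ordered
    ]
    dfi = sorted({(drug, ids[smi]) for drug, smi in dfi_raw})
    ffi = sorted({
        (ids[p], ids[c]) for p, kids in children_of.items() for c in kids
        if ids[p] != ids[c]
    })
    return FragmentationResult(fragments=fragments, dfi_edges=dfi,
                               ffi_edges=ffi)


def read_drug_table(path) -> list[DrugRecord]:
    """Read a two-column ``drug_id<TAB>smiles`` table, '#' comments ignored."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FragmentationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns")
            records.append(DrugRecord(parts[0], parts[1]))
    return records


def write_fragmentation(result: FragmentationResult, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "fragments.tsv"), "w", encoding="utf-8") as fh:
        for f in result.fragments:
            fh.write(f"{f.fragment_id}\t{f.canonical_smiles}\n")
    with open(os.path.join(outdir, "dfi.tsv"), "w", encoding="utf-8") as fh:
        for drug, frag in result.dfi_edges:
            fh.write(f"{drug}\t{frag}\n")
    with open(os.path.join(outdir, "ffi.tsv"), "w", encoding="utf-8") as fh:
        for p, c in result.ffi_edges:
            fh.write(f"{p}\t{c}\n")
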