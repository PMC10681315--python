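"""The drug-centric heterogeneous network and its cross-validation views.

The container holds one binary adjacency matrix per edge type, all indexed
by frozen per-type registries (string id -> dense 0-based index):

===========  =========================  ==========
matrix       edge type                  shape
===========  =========================  ==========
S            drug - drug                b x b (symmetric, zero diagonal)
Y            drug - fragment            b x F (directed)
Z            fragment - fragment        F x F (directed, parent -> child)
W            drug - target              b x n_targets
G            drug - side effect         b x n_side_effects
V            drug - disease             b x n_diseases
===========  =========================  ==========

A prediction task singles out one drug-related matrix R in {S, W, G, V}.
Cross-validation folds partition R's positive edges; the training *view*
of a fold substitutes the training-edge matrix for R everywhere (including
where the motif engine reads it), so no held-out edge can leak into the
hypergraphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fragmentation import FragmentationResult

TASK_KINDS = ("DDI", "DTI", "DDiI", "DSI")
#: which heterogeneous matrix the task's R stands in for
TASK_MATRIX = {"DDI": "S", "DTI": "W", "DSI": "G", "DDiI": "V"}

__all__ = [
    "Registry", "HeteroNetwork", "TaskNetwork", "FoldSplit", "NetworkView",
    "read_edge_list", "assemble_dsmn", "make_folds", "training_view",
    "TASK_KINDS", "TASK_MATRIX",
]


class Registry:
    """Ordered string-id <-> dense-index map (first-seen order, freezable)."""

    def __init__(self, ids=()):
        self._ids: list[str] = []
        self._index: dict[str, int] = {}
        self.frozen = False
        for i in ids:
            self.add(i)

    def add(self, id_: str) -> int:
        idx = self._index.get(id_)
        if idx is not None:
            return idx
        if self.frozen:
            raise KeyError(f"unknown id {id_!r} (registry frozen)")
        idx = len(self._ids)
        self._ids.append(id_)
        self._index[id_] = idx
        return idx

    def index(self, id_: str) -> int:
        try:
            return self._index[id_]
        except KeyError:
            raise KeyError(f"unknown id {id_!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def __len__(self):
        return len(self._ids)

    def __contains__(self, id_):
        return id_ in self._index


def read_edge_list(path, src_registry: Registry, dst_registry: Registry):
    """Read a two-column TSV edge list into deduplicated index pairs.

    Ids are auto-registered in first-seen order unless the registry is
    frozen, in which case a dangling id raises.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}")
            e = (src_registry.add(parts[0]), dst_registry.add(parts[1]))
            if e not in seen:
                seen.add(e)
                edges.append(e)
    return edges


@dataclass
class HeteroNetwork:
    """All typed adjacency matrices plus their node registries."""

    drugs: Registry
    fragments: Registry
    S: np.ndarray | None = None
    Y: np.ndarray | None = None
    Z: np.ndarray | None = None
    W: np.ndarray | None = None
    G: np.ndarray | None = None
    V: np.ndarray | None = None
    entity_registries: dict[str, Registry] = field(default_factory=dict)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def validate(self):
        b = self.n_drugs
        if self.S is not None:
            assert self.S.shape == (b, b)
            assert (self.S == self.S.T).all(), "S must be symmetric"
            assert (np.diag(self.S) == 0).all(), "S must have zero diagonal"
        for m in (self.S, self.Y, self.Z, self.W, self.G, self.V):
            if m is not None:
                assert ((m == 0) | (m == 1)).all(), "adjacency must be binary"


@dataclass
class TaskNetwork:
    """One prediction task: drugs vs drug-related entities."""

    kind: str
    R: np.ndarray  # b x t binary
    drugs: Registry
    entities: Registry

    @property
    def b(self) -> int:
        return self.R.shape[0]

    @property
    def t(self) -> int:
        return self.R.shape[1]

    def positive_edges(self) -> list[tuple[int, int]]:
        """Index pairs of observed interactions; (i, j) with i<j for DDI."""
        ii, jj = np.nonzero(self.R)
        if self.kind == "DDI":
            return [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]
        return [(int(i), int(j)) for i, j in zip(ii, jj)]


@dataclass
class FoldSplit:
    fold: int
    train_edges: list[tuple[int, int]]
    test_edges: list[tuple[int, int]]
    test_negatives: list[tuple[int, int]]
    seed: int


@dataclass
class NetworkView:
    """Per-fold training view: matrices the motif engine and encoder see."""

    S: np.ndarray | None
    Y: np.ndarray | None
    Z: np.ndarray | None
    W: np.ndarray | None
    G: np.ndarray | None
    V: np.ndarray | None
    R_train: np.ndarray
    task_kind: str


def _edges_to_matrix(edges, shape, symmetric=False) -> np.ndarray:
    m = np.zeros(shape, dtype=np.int64)
    for i, j in edges:
        m[i, j] = 1
        if symmetric:
            m[j, i] = 1
    if symmetric:
        np.fill_diagonal(m, 0)
    return m


def assemble_dsmn(frag: FragmentationResult | None,
                  task_kind: str,
                  task_edges: list[tuple[str, str]],
                  side_edges: dict[str, list[tuple[str, str]]] | None = None,
                  ) -> tuple[HeteroNetwork, TaskNetwork]:
    """Assemble the heterogeneous network and the task network.

    Parameters
    ----------
    frag : FragmentationResult or None
        Output of :func:`~hyperdrug.fragmentation.recursive_decompose`;
        None means no substructure information (Y, Z absent).
    task_kind : {"DDI", "DTI", "DDiI", "DSI"}
    task_edges : list of (drug_id, entity_id)
        String-id pairs of the task's observed interactions.
    side_edges : dict kind -> list of (drug_id, entity_id)
        Additional interaction networks (e.g. a DDI edge list providing S
        when the task is DTI).  The task's own kind may not reappear here.
    """
    if task_kind not in TASK_KINDS:
        raise ValueError(f"unknown task kind {task_kind!r}")
    side_edges = dict(side_edges or {})
    if task_kind in side_edges:
        raise ValueError(f"{task_kind} given both as task and side network")

    drugs = Registry()
    frag_drug_ids: set[str] = set()
    if frag is not None:
        for drug_id, _ in frag.dfi_edges:
            drugs.add(drug_id)
            frag_drug_ids.add(drug_id)
    for d, e in task_edges:
        drugs.add(d)
        if task_kind == "DDI":
            drugs.add(e)
    for kind, kind_edges in side_edges.items():
        for d, e in kind_edges:
            drugs.add(d)
            if kind == "DDI":
                drugs.add(e)

    missing = set(drugs.ids) - frag_drug_ids
    if frag is not None and missing:
        warnings.warn(
            f"{len(missing)} drug(s) without fragmentation get all-zero "
            f"substructure rows: {sorted(missing)[:5]}...",
            stacklevel=2)

    fragments = Registry()
    Y = Z = None
    if frag is not None:
        for node in frag.fragments:
            fragments.add(str(node.fragment_id))
        b, F = len(drugs), len(fragments)
        Y = np.zeros((b, F), dtype=np.int64)
        for drug_id, fid in frag.dfi_edges:
            Y[drugs.index(drug_id), fragments.index(str(fid))] = 1
        Z = np.zeros((F, F), dtype=np.int64)
        for p, c in frag.ffi_edges:
            Z[fragments.index(str(p)), fragments.index(str(c))] = 1

    b = len(drugs)
    entity_registries: dict[str, Registry] = {}
    matrices: dict[str, np.ndarray] = {}

    def build(kind: str, edges: list[tuple[str, str]]) -> np.ndarray:
        if kind == "DDI":
            idx = [(drugs.index(d), drugs.index(e)) for d, e in edges]
            return _edges_to_matrix(idx, (b, b), symmetric=True)
        reg = entity_registries.setdefault(kind, Registry())
        idx = [(drugs.index(d), reg.add(e)) for d, e in edges]
        return _edges_to_matrix(idx, (b, len(reg)))

    for kind, edges in side_edges.items():
        if kind not in TASK_KINDS:
            raise ValueError(f"unknown side-network kind {kind!r}")
        matrices[TASK_MATRIX[kind]] = build(kind, edges)

    for d, _ in task_edges:
        if d not in drugs:  # pragma: no cover - registered above
            raise KeyError(f"task edge references unknown drug {d!r}")
    R = build(task_kind, task_edges)
    matrices[TASK_MATRIX[task_kind]] = R

    hetero = HeteroNetwork(
        drugs=drugs, fragments=fragments,
        S=matrices.get("S"), Y=Y, Z=Z,
        W=matrices.get("W"), G=matrices.get("G"), V=matrices.get("V"),
        entity_registries=entity_registries,
    )
    hetero.validate()
    if task_kind == "DDI":
        entities = Registry(drugs.ids)
    else:
        entities = entity_registries[task_kind]
    task = TaskNetwork(kind=task_kind, R=R, drugs=drugs, entities=entities)
    return hetero, task


def _nonedge_sampler(task: TaskNetwork, forbidden: set, rng: np.random.Generator):
    b, t = task.R.shape

    def draw():
        while True:
            i = int(rng.integers(b))
            j = int(rng.integers(t))
            if task.kind == "DDI":
                if i == j:
                    continue
                i, j = (i, j) if i < j else (j, i)
            if (i, j) not in forbidden:
                return (i, j)

    return draw


def make_folds(task: TaskNetwork, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Edge-level k-fold partition with fixed 1:1 test negatives per fold.

    Test negatives are sampled uniformly from non-edges (never overlapping
    any known positive, in any fold) and are frozen with the fold so that
    metrics are comparable across epochs and models.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    positives = task.positive_edges()
    n = len(positives)
    if k > n:
        raise ValueError(f"k={k} exceeds number of positive edges ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    pos_set = set(positives)
    bounds = np.linspace(0, n, k + 1).astype(int)
    folds = []
    used_negs: set[tuple[int, int]] = set()
    for f in range(k):
        test_idx = set(order[bounds[f]:bounds[f + 1]].tolist())
        test = [positives[i] for i in sorted(test_idx)]
        train = [positives[i] for i in range(n) if i not in test_idx]
        draw = _nonedge_sampler(task, pos_set | used_negs, rng)
        negs = []
        for _ in range(len(test)):
            e = draw()
            used_negs.add(e)
            negs.append(e)
        train_set = set(train)
        assert not (set(test) & train_set)
        folds.append(FoldSplit(fold=f, train_edges=train, test_edges=test,
                               test_negatives=negs, seed=seed))
    return folds


def training_view(hetero: HeteroNetwork, task: TaskNetwork,
                  fold: FoldSplit) -> NetworkView:
    """Matrices visible during training of one fold.

    The task's own matrix (R, and S when the task is DDI) is rebuilt from
    the fold's training edges only; every other matrix passes through.
    """
    symmetric = task.kind == "DDI"
    R_train = _edges_to_matrix(fold.train_edges, task.R.shape,
                               symmetric=symmetric)
    mats = {"S": hetero.S, "Y": hetero.Y, "Z": hetero.Z,
            "W": hetero.W, "G": hetero.G, "V": hetero.V}
    mats[TASK_MATRIX[task.kind]] = R_train
    return NetworkView(S=mats["S"], Y=mats["Y"], Z=mats["Z"], W=mats["W"],
                       G=mats["G"], V=mats["V"], R_train=R_train,
                       task_kind=task.kind)


def full_view(hetero: HeteroNetwork, task: TaskNetwork) -> NetworkView:
    """View using all known edges (for final models / novel ranking)."""
    mats = {"S": hetero.S, "Y": hetero.Y, "Z": hetero.Z,
            "W": hetero.W, "G": hetero.G, "V": hetero.V}
    mats[TASK_MATRIX[task.kind]] = task.R
    return NetworkView(S=mats["S"], Y=mats["Y"], Z=mats["Z"], W=mats["W"],
                       G=mats["G"], V=mats["V"], R_train=task.R,
                       task_kind=task.kind)
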