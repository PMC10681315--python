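"""Motif-induced adjacency matrices and the four hypergraph incidences.

Twelve small typed subgraph patterns (triangles and quadrilaterals), each
anchored on a pair of drug nodes, define high-order drug relatedness: the
entry ``A_k[i, j]`` counts instances of motif ``M_k`` in which drugs i and
j co-occur (i != j).  The patterns split into four groups by two binary
semantics — are the anchor drugs directly interacting, and does the
evidence come from shared substructure or from shared molecular
interactions:

=======  =====================================  ===========================
group    motifs (matrix algebra)                meaning
=======  =====================================  ===========================
DRSS     A1=(SS)*S, A2=(YY')*S,                 related + same substructure
         A3=Am+Am' with Am=(YZY')*S
DISS     A4=SS, A5=YY', A6=Am+Am' (YZY')        independent + substructure
DRSM     A7=(WW')*S, A8=(GG')*S, A9=(VV')*S     related + same interactions
DISM     A10=WW', A11=GG', A12=VV'              independent + interactions
=======  =====================================  ===========================

(* is the elementwise product, ' the transpose.)  Diagonals are zeroed
after the algebra.  Every drug-independent count contains its drug-related
counterpart as the S-masked subset, so the redundancy is subtracted:
A4-A1, A5-A2, A6-A3, A10-A7, A11-A8, A12-A9.  Group sums give the branch
incidence matrices I_j (DRSS), I_p (DISS), I_i (DRSM), I_u (DISM); row d
of an incidence is the drug-d-centred hyperedge.

All arithmetic here is integer; a brute-force enumerator over explicit
node tuples provides the independent oracle for every pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkView

__all__ = [
    "MOTIF_GROUPS", "REDUNDANCY_PAIRS", "BranchIncidences",
    "motif_adjacency", "subtract_redundancy", "build_branch_incidences",
    "brute_force_motif_count",
]

#: branch label -> motif ids
MOTIF_GROUPS = {"j": (1, 2, 3), "p": (4, 5, 6), "i": (7, 8, 9),
                "u": (10, 11, 12)}
#: (independent, related) redundancy-subtraction pairs
REDUNDANCY_PAIRS = ((4, 1), (5, 2), (6, 3), (10, 7), (11, 8), (12, 9))

#: matrices each motif needs, in view-attribute names
_REQUIRES = {
    1: ("S",), 2: ("Y", "S"), 3: ("Y", "Z", "S"),
    4: ("S",), 5: ("Y",), 6: ("Y", "Z"),
    7: ("W", "S"), 8: ("G", "S"), 9: ("V", "S"),
    10: ("W",), 11: ("G",), 12: ("V",),
}


class MotifUnavailable(Exception):
    """A matrix required by this motif is absent from the view."""


def _get(view: NetworkView, k: int):
    vals = []
    for name in _REQUIRES[k]:
        m = getattr(view, name)
        if m is None:
            raise MotifUnavailable(f"motif M{k} needs matrix {name}")
        vals.append(np.asarray(m, dtype=np.int64))
    return vals


def motif_adjacency(view: NetworkView, k: int) -> np.ndarray:
    """The drug x drug co-occurrence count matrix A_k (diagonal zeroed)."""
    if k not in _REQUIRES:
        raise ValueError(f"motif id must be 1..12, got {k}")
    if k in (1, 4):
        (S,) = _get(view, 1) if k == 1 else _get(view, 4)
        A = S @ S
        if k == 1:
            A = A * S
    elif k in (2, 5):
        Y = _get(view, 5)[0]
        A = Y @ Y.T
        if k == 2:
            A = A * _get(view, 2)[1]
    elif k in (3, 6):
        Y, Z = _get(view, 6)
        Am = Y @ Z @ Y.T
        if k == 3:
            Am = Am * _get(view, 3)[2]
        A = Am + Am.T
    else:
        X = _get(view, k)[0]
        A = X @ X.T
        if k in (7, 8, 9):
            A = A * _get(view, k)[1]
    A = A.copy()
    np.fill_diagonal(A, 0)
    return A


def subtract_redundancy(independent: np.ndarray,
                        related: np.ndarray) -> np.ndarray:
    """Remove the drug-related instances from a drug-independent count.

    The related matrix is the independent one masked by the binary S, so
    the difference is non-negative by construction; a negative entry means
    the two matrices were not computed from the same view and is an error.
    """
    diff = independent - related
    if (diff < 0).any():
        raise AssertionError(
            "negative entry after redundancy subtraction — "
            "motif matrices inconsistent")
    return diff


@dataclass
class BranchIncidences:
    """The four incidence matrices with degree vectors and provenance."""

    I: dict[str, np.ndarray | None]
    degrees: dict[str, np.ndarray | None]
    contributing: dict[str, list[int]]

    @property
    def enabled(self) -> list[str]:
        return [x for x in "jpiu" if self.I[x] is not None]


def build_branch_incidences(view: NetworkView) -> BranchIncidences:
    """Group-sum the available motif matrices into I_j, I_p, I_i, I_u.

    A motif whose required matrices are absent is skipped; a group with no
    available motif yields a disabled branch (I = None) that the encoder
    must exclude and renormalize attention over.  DISS/DISM motifs are
    redundancy-subtracted against their DRSS/DRSM counterparts when the
    counterpart is computable (i.e. when S exists); without S there are no
    drug-related instances to remove.
    """
    A: dict[int, np.ndarray] = {}
    for k in range(1, 13):
        try:
            A[k] = motif_adjacency(view, k)
        except MotifUnavailable:
            pass
    for ind, rel in REDUNDANCY_PAIRS:
        if ind in A and rel in A:
            A[ind] = subtract_redundancy(A[ind], A[rel])
    I: dict[str, np.ndarray | None] = {}
    degrees: dict[str, np.ndarray | None] = {}
    contributing: dict[str, list[int]] = {}
    for x, ks in MOTIF_GROUPS.items():
        avail = [k for k in ks if k in A]
        contributing[x] = avail
        if not avail:
            I[x] = None
            degrees[x] = None
            continue
        Ix = sum(A[k] for k in avail)
        assert (Ix == Ix.T).all() and (np.diag(Ix) == 0).all()
        I[x] = Ix
        degrees[x] = Ix.sum(axis=1)
    return BranchIncidences(I=I, degrees=degrees, contributing=contributing)


# ---------------------------------------------------------------------------
# Brute-force oracle: explicit enumeration of typed motif instances
# ---------------------------------------------------------------------------

def brute_force_motif_count(view: NetworkView, k: int,
                            size_guard: int = 40) -> np.ndarray:
    """Count motif instances by exhaustive enumeration of node tuples.

    Deliberately loop-based and independent of the matrix algebra: for
    each ordered anchor pair (i, j) of distinct drugs it enumerates every
    admissible middle node (or node pair for the quadrilaterals) and
    checks the required edges one by one.  Intended for networks of a few
    dozen nodes per type.
    """
    mats = _get(view, k)  # raises MotifUnavailable like the fast path
    b = mats[0].shape[0] if k in (1, 4) else (
        mats[0].shape[0])
    if b > size_guard:
        raise ValueError(f"brute force limited to {size_guard} drugs")
    out = np.zeros((b, b), dtype=np.int64)

    if k in (1, 4):
        S = mats[0]
        for i in range(b):
            for j in range(b):
                if i == j:
                    continue
                n = sum(1 for m in range(b) if S[i, m] and S[m, j])
                if k == 1 and not S[i, j]:
                    n = 0
                out[i, j] = n
    elif k in (2, 5):
        Y = mats[0]
        S = mats[1] if k == 2 else None
        F = Y.shape[1]
        for i in range(b):
            for j in range(b):
                if i == j:
                    continue
                n = sum(1 for f in range(F) if Y[i, f] and Y[j, f])
                if k == 2 and not S[i, j]:
                    n = 0
                out[i, j] = n
    elif k in (3, 6):
        Y, Z = mats[0], mats[1]
        S = mats[2] if k == 3 else None
        F = Y.shape[1]
        for i in range(b):
            for j in range(b):
                if i == j:
                    continue
                # quadrilateral i - f - g - j with f -> g in Z, plus the
                # mirrored orientation (the algebra adds Am and its
                # transpose): count both (i,f,g,j) and (i,g,f,j) paths.
                n = 0
                for f in range(F):
                    for g in range(F):
                        if Y[i, f] and Z[f, g] and Y[j, g]:
                            n += 1
                        if Y[i, f] and Z[g, f] and Y[j, g]:
                            n += 1
                if k == 3 and not S[i, j]:
                    n = 0
                out[i, j] = n
    else:
        X = mats[0]
        S = mats[1] if k in (7, 8, 9) else None
        t = X.shape[1]
        for i in range(b):
            for j in range(b):
                if i == j:
                    continue
                n = sum(1 for e in range(t) if X[i, e] and X[j, e])
                if k in (7, 8, 9) and not S[i, j]:
                    n = 0
                out[i, j] = n
    return out
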