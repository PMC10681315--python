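"""Drug/entity embedding encoder.

Drugs start from a shared embedding table D0 (b x c) and entities from M0
(t x c).  Four branches — one per motif-driven hypergraph — each pass a
self-gated copy of D0 through L hypergraph-attention layers:

    D0x   = D0 * sigmoid(D0 Pgx + Bgx)                     (self-gate)
    D'    = rowsoftmax(Ix Dl Dl') Dl
    Dl+1  = Dx^-1 relu(D' Pmx + Bmx)                       (Dx = row sums of Ix)
    Dx    = mean(D0x .. DLx)                               (anti-oversmoothing)

Per-drug branch attention then fuses the four branch embeddings into Ds,
and a bipartite graph convolution on the task matrix R mixes in entity
information:

    D0c   = gate(D0);      M0 = entity table (ungated)
    Dl+1c = degrow(R)^-1 relu((R  Ml ) Pmc + bmc)
    Dlm   = sum_x wx * Dlx + 1/2 Dlc
    Ml+1  = degcol(R)^-1 relu((R' Dlm) Ptc + btc)
    D     = Ds + mean_l Dlm,    M = mean_l Ml

Zero-degree rows use the pseudo-inverse convention 1/0 := 0: an isolated
drug contributes no hypergraph signal but still receives the convolution
signal.  A disabled branch (no available motif) is excluded from the
attention softmax.  Interaction scores are row inner products D_d . M_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["EncoderConfig", "EncoderParams", "forward", "ForwardState",
           "self_gate", "hypergraph_attention_layer", "branch_forward",
           "branch_attention", "gcn_forward", "score_pairs"]

BRANCHES = ("j", "p", "i", "u")


@dataclass
class EncoderConfig:
    dim: int = 100
    layers: int = 2
    masked_softmax: bool = False
    propagation_params: bool = True
    attention: str = "softmax"  # "softmax" (Eq.-style) or "conv" ablation
    branches: tuple[str, ...] = BRANCHES
    seed: int = 0


class EncoderParams:
    """All trainable arrays, as an ordered name -> ndarray mapping.

    Nine self-gates (four branch input gates, one convolution gate, four
    self-supervised readout gates), the two embedding tables, branch and
    convolution propagation blocks, and the branch-attention parameters.
    When ``propagation_params`` is off the propagation blocks are fixed at
    identity/zero and excluded from the trainable set.
    """

    def __init__(self, b: int, t: int, config: EncoderConfig):
        c = config.dim
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.b, self.t, self.c = b, t, c

        def xavier(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        p: dict[str, np.ndarray] = {}
        p["D0"] = rng.uniform(-0.05, 0.05, size=(b, c)) / np.sqrt(c)
        p["M0"] = rng.uniform(-0.05, 0.05, size=(t, c)) / np.sqrt(c)
        for x in BRANCHES:
            p[f"P_g_{x}"] = xavier(c, c)
            p[f"B_g_{x}"] = np.zeros(c)
            p[f"P_sg_{x}"] = xavier(c, c)
            p[f"b_sg_{x}"] = np.zeros(c)
        p["P_g_c"] = xavier(c, c)
        p["b_g_c"] = np.zeros(c)
        if config.propagation_params:
            for x in BRANCHES:
                p[f"P_m_{x}"] = xavier(c, c)
                p[f"B_m_{x}"] = np.zeros(c)
            p["P_m_c"] = xavier(c, c)
            p["b_m_c"] = np.zeros(c)
            p["P_t_c"] = xavier(c, c)
            p["b_t_c"] = np.zeros(c)
        p["a"] = xavier(c, 1)[:, 0]
        p["P_a"] = xavier(c, c)
        self.values = p

    def tensors(self) -> dict[str, Tensor]:
        """Fresh leaf tensors for one forward/backward pass."""
        out = {k: Tensor(v, requires_grad=True) for k, v in self.values.items()}
        if not self.config.propagation_params:
            eye = np.eye(self.c)
            zero = np.zeros(self.c)
            for x in BRANCHES:
                out[f"P_m_{x}"] = Tensor(eye)
                out[f"B_m_{x}"] = Tensor(zero)
            out["P_m_c"] = Tensor(eye)
            out["b_m_c"] = Tensor(zero)
            out["P_t_c"] = Tensor(eye)
            out["b_t_c"] = Tensor(zero)
        return out

    def names(self) -> list[str]:
        return list(self.values)


def _deg_inv(deg: np.ndarray) -> np.ndarray:
    """Column vector of 1/deg with the 1/0 := 0 convention."""
    with np.errstate(divide="ignore"):
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
    return inv[:, None]


def self_gate(X: Tensor, P: Tensor, B: Tensor) -> Tensor:
    """X * sigmoid(X P + B): feature-wise re-weighting of a shared table."""
    return ad.mul(X, ad.sigmoid(ad.add(ad.matmul(X, P), B)))


def hypergraph_attention_layer(I_x: np.ndarray, deg: np.ndarray, D_l: Tensor,
                               P_m: Tensor, B_m: Tensor,
                               masked: bool = False,
                               attention: str = "softmax") -> Tensor:
    """One propagation layer on a drug hypergraph incidence.

    ``attention="softmax"`` is the attention form (row softmax of
    I D D'); ``"conv"`` drops the softmax and propagates I D directly,
    i.e. a degree-normalized hypergraph convolution.
    """
    if not np.isfinite(D_l.value).all():
        raise ValueError("non-finite embeddings entering attention layer")
    I_t = np.asarray(I_x, dtype=np.float64)
    if attention == "softmax":
        scores = ad.matmul(ad.matmul(I_t, D_l), ad.transpose(D_l))
        attn = ad.row_softmax(scores, mask=(I_t > 0) if masked else None)
        Dp = ad.matmul(attn, D_l)
    elif attention == "conv":
        Dp = ad.matmul(I_t, D_l)
    else:
        raise ValueError(f"unknown attention mode {attention!r}")
    out = ad.relu(ad.add(ad.matmul(Dp, P_m), B_m))
    return ad.mul(out, _deg_inv(deg))


def branch_forward(I_x: np.ndarray, deg: np.ndarray, D0: Tensor,
                   P_g: Tensor, B_g: Tensor, P_m: Tensor, B_m: Tensor,
                   L: int, masked: bool = False,
                   attention: str = "softmax") -> tuple[Tensor, list[Tensor]]:
    """Gate, propagate L layers, and layer-average one branch."""
    if L < 1:
        raise ValueError("L must be >= 1")
    layers = [self_gate(D0, P_g, B_g)]
    for _ in range(L):
        layers.append(hypergraph_attention_layer(
            I_x, deg, layers[-1], P_m, B_m, masked=masked,
            attention=attention))
    mean = ad.scale(sum(layers[1:], layers[0]), 1.0 / (L + 1))
    return mean, layers


def branch_attention(branch_means: dict[str, Tensor], a: Tensor,
                     P_a: Tensor) -> tuple[dict[str, Tensor], Tensor]:
    """Per-drug softmax over branches; returns weights and the fusion Ds."""
    enabled = list(branch_means)
    if not enabled:
        raise ValueError("all hypergraph branches disabled")
    a_col = ad.reshape(a, (-1, 1))
    scores = [ad.reshape(ad.matmul(ad.matmul(branch_means[x], P_a), a_col),
                         (-1,)) for x in enabled]
    omega = ad.row_softmax(ad.stack_cols(scores))
    b = omega.shape[0]
    weights: dict[str, Tensor] = {}
    Ds = None
    for col, x in enumerate(enabled):
        e = np.zeros((len(enabled), 1))
        e[col, 0] = 1.0
        w = ad.matmul(omega, e)  # b x 1 column of omega
        weights[x] = w
        term = ad.mul(w, branch_means[x])
        Ds = term if Ds is None else ad.add(Ds, term)
    return weights, Ds


def gcn_forward(R: np.ndarray, D0_gated: Tensor, M0: Tensor,
                omega: dict[str, Tensor], branch_layers: dict[str, list[Tensor]],
                P_m_c: Tensor, b_m_c: Tensor, P_t_c: Tensor, b_t_c: Tensor,
                L: int) -> tuple[list[Tensor], list[Tensor], list[Tensor]]:
    """Bipartite convolution on R fused with the per-layer branch signal.

    Returns (Dc_layers, Dm_layers, M_layers), each of length L+1.
    """
    R = np.asarray(R, dtype=np.float64)
    if R.size == 0:
        raise ValueError("task matrix R is empty")
    row_inv = _deg_inv(R.sum(axis=1))
    col_inv = _deg_inv(R.sum(axis=0))
    Dc = [D0_gated]
    M = [M0]
    Dm: list[Tensor] = []
    for l in range(L + 1):
        fused = None
        for x, w in omega.items():
            term = ad.mul(w, branch_layers[x][l])
            fused = term if fused is None else ad.add(fused, term)
        half_dc = ad.scale(Dc[l], 0.5)
        Dm.append(half_dc if fused is None else ad.add(fused, half_dc))
        if l < L:
            Dc.append(ad.mul(
                ad.relu(ad.add(ad.matmul(ad.matmul(Tensor(R), M[l]), P_m_c),
                               b_m_c)),
                row_inv))
            M.append(ad.mul(
                ad.relu(ad.add(ad.matmul(ad.matmul(Tensor(R.T), Dm[l]),
                                         P_t_c), b_t_c)),
                col_inv))
    return Dc, Dm, M


@dataclass
class ForwardState:
    """Everything a loss or a diagnostic needs from one forward pass."""

    D: Tensor
    M: Tensor
    Ds: Tensor | None
    omega: dict[str, Tensor]
    branch_means: dict[str, Tensor]
    branch_layers: dict[str, list[Tensor]]
    tensors: dict[str, Tensor] = field(default_factory=dict)


def forward(params: EncoderParams, incidences, R: np.ndarray,
            config: EncoderConfig | None = None) -> ForwardState:
    """Full encoder pass: branches, attention fusion, convolution, Eq.-7 sums.

    ``incidences`` is a :class:`~hyperdrug.motifs.BranchIncidences`; only
    branches listed in the config *and* enabled there participate.  With no
    enabled branch (the no-hypergraph ablation) Ds is zero and the model
    reduces to the gated bipartite convolution.
    """
    config = config or params.config
    L = config.layers
    t = params.tensors()
    enabled = [x for x in config.branches
               if incidences.I.get(x) is not None]

    branch_means: dict[str, Tensor] = {}
    branch_layers: dict[str, list[Tensor]] = {}
    for x in enabled:
        mean, layers = branch_forward(
            incidences.I[x], incidences.degrees[x], t["D0"],
            t[f"P_g_{x}"], t[f"B_g_{x}"], t[f"P_m_{x}"], t[f"B_m_{x}"],
            L, masked=config.masked_softmax, attention=config.attention)
        branch_means[x] = mean
        branch_layers[x] = layers

    if branch_means:
        omega, Ds = branch_attention(branch_means, t["a"], t["P_a"])
    else:
        omega, Ds = {}, None

    D0c = self_gate(t["D0"], t["P_g_c"], t["b_g_c"])
    _, Dm_layers, M_layers = gcn_forward(
        R, D0c, t["M0"], omega, branch_layers,
        t["P_m_c"], t["b_m_c"], t["P_t_c"], t["b_t_c"], L)

    Dm_mean = ad.scale(sum(Dm_layers[1:], Dm_layers[0]), 1.0 / (L + 1))
    D = Dm_mean if Ds is None else ad.add(Ds, Dm_mean)
    M = ad.scale(sum(M_layers[1:], M_layers[0]), 1.0 / (L + 1))
    return ForwardState(D=D, M=M, Ds=Ds, omega=omega,
                        branch_means=branch_means,
                        branch_layers=branch_layers, tensors=t)


def score_pairs(D: Tensor, M: Tensor, drug_idx, entity_idx) -> Tensor:
    """Inner-product scores s_hat[d, i] for index-aligned pairs."""
    drug_idx = np.asarray(drug_idx, dtype=np.intp)
    entity_idx = np.asarray(entity_idx, dtype=np.intp)
    if drug_idx.size and (drug_idx.max() >= D.shape[0]
                          or entity_idx.max() >= M.shape[0]):
        raise IndexError("pair index out of range")
    dd = ad.gather_rows(D, drug_idx)
    mm = ad.gather_rows(M, entity_idx)
    return ad.tsum(ad.mul(dd, mm), axis=1)
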