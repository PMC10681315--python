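"""Training objective and optimization loop.

Two terms are combined.  The ranking term is Bayesian Personalized
Ranking over triples (d, i, j) — drug d, observed partner i, sampled
unobserved partner j:

    L_s = sum -log sigmoid(s[d,i] - s[d,j]) + delta * ||theta||_2^2

The auxiliary term is a hierarchical mutual-information loss in the style
of Deep Graph Infomax: per branch, a gated copy of the final drug table is
summarized into drug-centred sub-hypergraph vectors s_d (weighted mean of
hyperedge members) and a graph summary g (mean of the s_d); a corrupted
summary table (row- then column-shuffled) provides negatives, and a
pairwise ranking discriminator (inner product) scores agreement at both
the node-subgraph and subgraph-graph levels:

    L_self = -sum_x sum_d [ log sigmoid(f(d_d, s_d) - f(d_d, s~_d))
                          + log sigmoid(f(s_d, g)   - f(s~_d, g)) ]

The total objective is L = L_s + lambda * L_self, minimized with Adam
(the "adaptive learning rate" optimizer) at initial rate 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import (BRANCHES, EncoderConfig, EncoderParams, ForwardState,
                      forward, score_pairs, self_gate)
from .motifs import BranchIncidences

__all__ = [
    "TrainConfig", "ABLATIONS", "sample_triples", "bpr_loss",
    "subhypergraph_readout", "corrupt_perms", "ssl_loss", "total_loss",
    "Adam", "train", "TrainResult", "build_loss",
]

#: ablation name -> encoder/loss overrides
ABLATIONS = {
    "full": {},
    "no_hyper": {"branches": ()},          # no hypergraph branches
    "frag_only": {"branches": ("j", "p")},  # substructure groups only
    "mol_only": {"branches": ("i", "u")},   # molecular-interaction groups
    "conv": {"attention": "conv"},          # convolution instead of attention
    "no_ssl": {"lam": 0.0},                 # drop the auxiliary task
}


@dataclass
class TrainConfig:
    """Hyperparameters; defaults are the published operating point."""

    dim: int = 100          # embedding dimension c
    layers: int = 2         # propagation depth L
    reg: float = 0.01       # L2 coefficient delta
    lam: float = 0.001      # auxiliary-loss weight lambda
    batch: int = 2000
    lr: float = 0.001
    epochs: int = 200
    seed: int = 0
    ablation: str = "full"
    masked_softmax: bool = False
    propagation_params: bool = True

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"choose from {sorted(ABLATIONS)}")
        for name in ("dim", "layers", "batch", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def encoder_config(self) -> EncoderConfig:
        over = ABLATIONS[self.ablation]
        return EncoderConfig(
            dim=self.dim, layers=self.layers,
            masked_softmax=self.masked_softmax,
            propagation_params=self.propagation_params,
            attention=over.get("attention", "softmax"),
            branches=over.get("branches", BRANCHES),
            seed=self.seed)

    @property
    def effective_lam(self) -> float:
        return ABLATIONS[self.ablation].get("lam", self.lam)


def sample_triples(R_train: np.ndarray, n: int, rng: np.random.Generator,
                   symmetric: bool = False) -> np.ndarray:
    """Draw n BPR triples (d, i, j) uniformly, with replacement.

    (d, i) comes from the observed entries of R_train; j is uniform over
    the entities unobserved for d.  A drug with a fully observed row
    cannot yield a negative and is skipped with a warning (another edge is
    drawn instead).
    """
    R = np.asarray(R_train)
    b, t = R.shape
    dd, ii = np.nonzero(R)
    if n == 0 or dd.size == 0:
        return np.empty((0, 3), dtype=np.intp)
    full_rows = set()
    for d in range(b):
        row = R[d].astype(bool).copy()
        if symmetric:
            row[d] = True
        if row.all():
            full_rows.add(d)
    if full_rows:
        import warnings
        warnings.warn(f"{len(full_rows)} drug(s) have fully observed rows; "
                      "their edges are skipped in BPR sampling", stacklevel=2)
    out = np.empty((n, 3), dtype=np.intp)
    k = 0
    while k < n:
        e = int(rng.integers(dd.size))
        d, i = int(dd[e]), int(ii[e])
        if d in full_rows:
            continue
        while True:
            j = int(rng.integers(t))
            if R[d, j] == 0 and not (symmetric and j == d):
                break
        out[k] = (d, i, j)
        k += 1
    return out


def bpr_loss(triples: np.ndarray, D: Tensor, M: Tensor,
             theta: list[Tensor] | None = None, delta: float = 0.0) -> Tensor:
    """Pairwise ranking loss plus L2 penalty on the parameter blocks."""
    triples = np.asarray(triples, dtype=np.intp).reshape(-1, 3)
    s_pos = score_pairs(D, M, triples[:, 0], triples[:, 1])
    s_neg = score_pairs(D, M, triples[:, 0], triples[:, 2])
    margin = ad.sub(s_pos, s_neg)
    if not np.isfinite(margin.value).all():
        raise ValueError("non-finite scores in BPR loss")
    loss = ad.tsum(ad.softplus(ad.neg(margin)))
    if theta and delta:
        reg = None
        for p in theta:
            term = ad.tsum(ad.mul(p, p))
            reg = term if reg is None else ad.add(reg, term)
        loss = ad.add(loss, ad.scale(reg, delta))
    return loss


def subhypergraph_readout(D_ssl: Tensor, I_x: np.ndarray
                          ) -> tuple[Tensor, np.ndarray]:
    """Weighted-mean summaries s_d = (I_x[d] . D_ssl) / #nonzeros(I_x[d]).

    Weights are kept as-is; the divisor counts hyperedge members, not
    total weight.  Returns the b x c summary table and the boolean mask of
    drugs with a non-empty hyperedge row (only those enter the loss).
    """
    I_f = np.asarray(I_x, dtype=np.float64)
    nnz = (I_f > 0).sum(axis=1)
    valid = nnz > 0
    inv = np.where(valid, 1.0 / np.maximum(nnz, 1), 0.0)[:, None]
    S = ad.mul(ad.matmul(Tensor(I_f), D_ssl), inv)
    return S, valid


def corrupt_perms(b: int, rng: np.random.Generator, c: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Row and column permutations used to corrupt a summary table."""
    return rng.permutation(b), rng.permutation(c)


def ssl_loss(D: Tensor, tensors: dict[str, Tensor],
             incidences: BranchIncidences, enabled: list[str],
             perms: dict[str, tuple[np.ndarray, np.ndarray]]) -> Tensor:
    """Hierarchical mutual-information loss over the enabled branches."""
    total = None
    for x in enabled:
        I_x = incidences.I[x]
        D_ssl = self_gate(D, tensors[f"P_sg_{x}"], tensors[f"b_sg_{x}"])
        S, valid = subhypergraph_readout(D_ssl, I_x)
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue
        mrow = (valid.astype(np.float64) / n_valid)[None, :]
        g = ad.matmul(Tensor(mrow), S)  # 1 x c graph summary
        S_neg = ad.permute(S, *perms[x])
        vmask = valid.astype(np.float64)
        diff_node = ad.tsum(ad.mul(D_ssl, ad.sub(S, S_neg)), axis=1)
        diff_graph = ad.tsum(ad.mul(ad.sub(S, S_neg), g), axis=1)
        term = ad.add(ad.tsum(ad.mul(ad.softplus(ad.neg(diff_node)), vmask)),
                      ad.tsum(ad.mul(ad.softplus(ad.neg(diff_graph)), vmask)))
        total = term if total is None else ad.add(total, term)
    if total is None:
        return Tensor(0.0)
    return total


def total_loss(L_s: Tensor, L_self: Tensor, lam: float) -> Tensor:
    """L = L_s + lambda * L_self."""
    if lam == 0.0:
        return L_s
    return ad.add(L_s, ad.scale(L_self, lam))


def build_loss(params: EncoderParams, incidences: BranchIncidences,
               R_train: np.ndarray, triples: np.ndarray,
               perms: dict[str, tuple[np.ndarray, np.ndarray]],
               config: TrainConfig) -> tuple[Tensor, Tensor, Tensor,
                                             ForwardState]:
    """One deterministic forward pass -> (total, bpr, ssl, state).

    Deterministic given fixed triples and corruption permutations, which
    makes it directly checkable against finite differences.
    """
    enc = config.encoder_config()
    state = forward(params, incidences, R_train, enc)
    theta = [t for t in state.tensors.values() if t.requires_grad]
    L_s = bpr_loss(triples, state.D, state.M, theta, config.reg)
    enabled = [x for x in enc.branches if incidences.I.get(x) is not None]
    lam = config.effective_lam
    if lam != 0.0 and enabled:
        L_self = ssl_loss(state.D, state.tensors, incidences, enabled, perms)
    else:
        L_self = Tensor(0.0)
    return total_loss(L_s, L_self, lam), L_s, L_self, state


class Adam:
    """Adaptive-moment optimizer over a name -> ndarray parameter dict."""

    def __init__(self, values: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.values = values
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in values.items()}
        self.v = {k: np.zeros_like(v) for k, v in values.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.values[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    params: EncoderParams
    trace: list[dict] = field(default_factory=list)  # per-epoch losses


def train(incidences: BranchIncidences, R_train: np.ndarray,
          config: TrainConfig, symmetric: bool | None = None,
          t_entities: int | None = None) -> TrainResult:
    """Fit the encoder on one training view.

    One epoch draws one triple per observed training edge, split into
    minibatches of ``config.batch``; every minibatch runs a full-graph
    forward pass and one Adam step on the total objective.  Evaluation
    negatives are *not* touched here — they live with the fold split.
    """
    R_train = np.asarray(R_train)
    b, t = R_train.shape
    t = t_entities if t_entities is not None else t
    symmetric = (b == t and (R_train == R_train.T).all()
                 ) if symmetric is None else symmetric
    enc = config.encoder_config()
    params = EncoderParams(b, t, enc)
    opt = Adam(params.values, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    n_edges = int(np.count_nonzero(R_train))
    if n_edges == 0:
        raise ValueError("no training edges")
    enabled = [x for x in enc.branches if incidences.I.get(x) is not None]
    trace = []
    for epoch in range(config.epochs):
        triples = sample_triples(R_train, n_edges, rng, symmetric=symmetric)
        e_bpr = e_ssl = e_tot = 0.0
        for lo in range(0, len(triples), config.batch):
            batch = triples[lo:lo + config.batch]
            perms = {x: corrupt_perms(b, rng, params.c) for x in enabled}
            L, L_s, L_self, state = build_loss(
                params, incidences, R_train, batch, perms, config)
            if not np.isfinite(L.value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // config.batch}")
            L.backward()
            grads = {k: state.tensors[k].grad for k in params.values
                     if state.tensors[k].requires_grad}
            opt.step(grads)
            e_bpr += float(L_s.value)
            e_ssl += float(L_self.value)
            e_tot += float(L.value)
        trace.append({"epoch": epoch, "loss_bpr": e_bpr, "loss_ssl": e_ssl,
                      "loss_total": e_tot})
    return TrainResult(params=params, trace=trace)
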