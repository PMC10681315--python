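"""Cross-validated metrics, novel-interaction ranking, drug similarity."""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import DrugLinkModel, DrugLinkResults
from .network import FoldSplit, make_folds

__all__ = ["auroc_aupr", "cross_validate", "CVResult", "rank_novel",
           "drug_similarity"]


def auroc_aupr(pos_scores, neg_scores) -> tuple[float, float]:
    """AUROC (ties count one half) and step-integrated AUPR.

    AUROC is the rank statistic P(score+ > score-) with tie correction;
    AUPR uses step-wise precision-recall summation (no linear
    interpolation between operating points).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


@dataclass
class CVResult:
    per_fold: list[dict] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean([f["auroc"] for f in self.per_fold]))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean([f["aupr"] for f in self.per_fold]))

    @property
    def sd_auroc(self) -> float:
        return float(np.std([f["auroc"] for f in self.per_fold], ddof=1))

    @property
    def sd_aupr(self) -> float:
        return float(np.std([f["aupr"] for f in self.per_fold], ddof=1))

    def as_dict(self) -> dict:
        return {"folds": self.per_fold,
                "mean": {"auroc": self.mean_auroc, "aupr": self.mean_aupr},
                "sd": {"auroc": self.sd_auroc, "aupr": self.sd_aupr}}


def _fold_metrics(results: DrugLinkResults, fold: FoldSplit) -> dict:
    pos = results.predict(fold.test_edges)
    neg = results.predict(fold.test_negatives)
    auroc, aupr = auroc_aupr(pos, neg)
    return {"fold": fold.fold, "auroc": auroc, "aupr": aupr}


def cross_validate(model: DrugLinkModel, k: int = 5, seed: int = 0,
                   untrained: bool = False) -> CVResult:
    """k-fold CV: per fold, rebuild hypergraphs from the training view,
    train, and score held-out positives against the fold's fixed negatives.

    With ``untrained=True`` the randomly initialized (epoch-0) encoder is
    scored instead — the no-learning baseline.
    """
    folds = make_folds(model.task, k=k, seed=seed)
    out = CVResult()
    for fold in folds:
        if untrained:
            res = model.initial_results(fold=fold, seed=seed)
        else:
            res = model.fit(fold=fold, seed=seed)
        out.per_fold.append(_fold_metrics(res, fold))
    return out


def rank_novel(results: DrugLinkResults, top_n: int = 20) -> list[dict]:
    """Top unobserved pairs by score, all known edges removed.

    Ties break deterministically: score descending, then drug index, then
    entity index.  For a DDI task only pairs i < j are candidates.
    """
    task = results.model.task
    scores = results.score_matrix()
    known = np.asarray(task.R, dtype=bool)
    b, t = scores.shape
    cand = ~known
    if task.kind == "DDI":
        cand &= np.triu(np.ones((b, t), dtype=bool), k=1)
    ii, jj = np.nonzero(cand)
    if ii.size == 0:
        return []
    if top_n > ii.size:
        warnings.warn(f"top_n={top_n} exceeds {ii.size} candidate pairs; "
                      "returning all", stacklevel=2)
        top_n = ii.size
    vals = scores[ii, jj]
    order = np.lexsort((jj, ii, -vals))[:top_n]
    drug_ids = task.drugs.ids
    entity_ids = task.entities.ids
    return [{"drug": drug_ids[ii[o]], "entity": entity_ids[jj[o]],
             "drug_idx": int(ii[o]), "entity_idx": int(jj[o]),
             "score": float(vals[o]), "rank": r + 1}
            for r, o in enumerate(order)]


def drug_similarity(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cosine similarity between drug embeddings + nearest neighbor.

    Zero rows have undefined direction: their similarities are set to 0
    and their neighbor index to -1.
    """
    D = np.asarray(D, dtype=float)
    norms = np.linalg.norm(D, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    U = D / safe[:, None]
    sim = U @ U.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    masked = sim.copy()
    np.fill_diagonal(masked, -np.inf)
    nn = masked.argmax(axis=1)
    nn[zero] = -1
    return sim, nn
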