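"""Model / Results objects tying the pipeline together.

:class:`DrugLinkModel` is built from a task network plus the heterogeneous
side information (fragments, side interaction networks); ``fit()`` builds
the motif hypergraphs from the visible edges, trains the encoder, and
returns a :class:`DrugLinkResults` carrying the embeddings, the loss
trace, and prediction / ranking / similarity methods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fragmentation import FragmentationResult
from .motifs import BranchIncidences, build_branch_incidences
from .network import (FoldSplit, HeteroNetwork, NetworkView, TaskNetwork,
                      assemble_dsmn, full_view, training_view)
from .objective import TrainConfig, TrainResult, train
from .encoder import forward

__all__ = ["DrugLinkModel", "DrugLinkResults"]


class DrugLinkModel:
    """Hypergraph-attention link predictor for one drug-related task.

    Parameters
    ----------
    task : TaskNetwork
        The drug x entity interaction matrix to be predicted.
    hetero : HeteroNetwork
        The assembled heterogeneous network providing S, Y, Z and any side
        interaction matrices for motif construction.
    config : TrainConfig
        Hyperparameters; defaults are the published operating point.
    """

    def __init__(self, task: TaskNetwork, hetero: HeteroNetwork,
                 config: TrainConfig | None = None):
        self.task = task
        self.hetero = hetero
        self.config = config or TrainConfig()

    @classmethod
    def from_edge_lists(cls, task_kind: str,
                        task_edges: list[tuple[str, str]],
                        frag: FragmentationResult | None = None,
                        side_edges=None,
                        config: TrainConfig | None = None) -> "DrugLinkModel":
        hetero, task = assemble_dsmn(frag, task_kind, task_edges, side_edges)
        return cls(task, hetero, config)

    def _view(self, fold: FoldSplit | None) -> NetworkView:
        if fold is None:
            return full_view(self.hetero, self.task)
        return training_view(self.hetero, self.task, fold)

    def fit(self, fold: FoldSplit | None = None,
            seed: int | None = None) -> "DrugLinkResults":
        """Build hypergraphs from the visible edges and train the encoder.

        With a fold, only its training edges are visible anywhere in the
        model (hypergraphs included); without one, all known edges are
        used — appropriate for novel-interaction ranking.
        """
        config = self.config if seed is None else replace(self.config,
                                                          seed=seed)
        view = self._view(fold)
        incidences = build_branch_incidences(view)
        result = train(incidences, view.R_train, config,
                       symmetric=self.task.kind == "DDI",
                       t_entities=self.task.t)
        return DrugLinkResults(self, fold, view, incidences, result, config)

    def initial_results(self, fold: FoldSplit | None = None,
                        seed: int | None = None) -> "DrugLinkResults":
        """Epoch-0 (untrained) results: the random-initialization baseline."""
        config = replace(self.config, epochs=1,
                         seed=self.config.seed if seed is None else seed)
        view = self._view(fold)
        incidences = build_branch_incidences(view)
        from .encoder import EncoderParams
        params = EncoderParams(view.R_train.shape[0], self.task.t,
                               config.encoder_config())
        return DrugLinkResults(self, fold, view, incidences,
                               TrainResult(params=params, trace=[]), config)


@dataclass
class DrugLinkResults:
    """Fitted state: embeddings, losses, and downstream predictions."""

    model: DrugLinkModel
    fold: FoldSplit | None
    view: NetworkView
    incidences: BranchIncidences
    train_result: TrainResult
    config: TrainConfig

    def __post_init__(self):
        state = forward(self.train_result.params, self.incidences,
                        self.view.R_train, self.config.encoder_config())
        self.D = state.D.value
        self.M = state.M.value
        self.omega = {x: w.value[:, 0] for x, w in state.omega.items()}

    @property
    def params(self):
        return self.train_result.params

    @property
    def loss_trace(self):
        return self.train_result.trace

    def score_matrix(self) -> np.ndarray:
        """Inner-product scores for every (drug, entity) pair."""
        return self.D @ self.M.T

    def predict(self, pairs) -> np.ndarray:
        """Scores for index pairs [(drug_idx, entity_idx), ...]."""
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        return np.einsum("ij,ij->i", self.D[pairs[:, 0]], self.M[pairs[:, 1]])

    def summary(self) -> str:
        """Plain-text fit report in the style of statistical model results."""
        task = self.model.task
        lines = [
            "Drug link prediction model",
            "=" * 58,
            f"Task:               {task.kind} "
            f"({task.b} drugs x {task.t} entities)",
            f"Positive edges:     {int(np.count_nonzero(task.R))}",
            f"Enabled branches:   {', '.join(self.incidences.enabled) or 'none'}",
            f"Embedding dim:      {self.config.dim}",
            f"Layers:             {self.config.layers}",
            f"Ablation:           {self.config.ablation}",
            f"Epochs run:         {len(self.loss_trace)}",
        ]
        if self.loss_trace:
            first, last = self.loss_trace[0], self.loss_trace[-1]
            lines += [
                f"Loss (first epoch): {first['loss_total']:.4f} "
                f"(BPR {first['loss_bpr']:.4f}, SSL {first['loss_ssl']:.4f})",
                f"Loss (last epoch):  {last['loss_total']:.4f} "
                f"(BPR {last['loss_bpr']:.4f}, SSL {last['loss_ssl']:.4f})",
            ]
        if self.omega:
            mean_w = {x: float(np.mean(w)) for x, w in self.omega.items()}
            lines.append("Mean branch attention: " + ", ".join(
                f"{x}={v:.3f}" for x, v in mean_w.items()))
        lines.append("=" * 58)
        return "\n".join(lines)
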