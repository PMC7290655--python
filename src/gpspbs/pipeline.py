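"""The staged training pipeline: PWD -> PVT -> classifier, bundled per node.

A :class:`PredictorNode` is the deployable unit of the predictor: the
positive peptides of one hierarchy node, the optimized position weights,
the trained network, and (after calibration) the FPR threshold table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data_model import BenchmarkDataset, HierarchyNode, PBPItem
from .dnn import DNNConfig, TrainedModel, fine_tune, train_dnn
from .pvt import encode_items
from .pwd import determine_weights, fit_plr_weights
from .scoring import PositionWeights, SubstitutionMatrix


@dataclass
class PredictorNode:
    """A trained model plus calibrated thresholds attached to one hierarchy node."""

    node: HierarchyNode
    m: int
    n: int
    positives: list[str]  # positive peptide windows defining the profile
    weights: PositionWeights
    matrix: SubstitutionMatrix
    model: TrainedModel
    thresholds: "object | None" = None  # ThresholdTable once calibrated
    parent: "PredictorNode | None" = None

    @property
    def window_length(self) -> int:
        return self.m + 1 + self.n

    def encode(self, items) -> np.ndarray:
        return encode_items(items, self.positives, self.weights, self.matrix)

    def score(self, items) -> np.ndarray:
        """Probability scores for a list of peptide windows (items or strings)."""
        items = list(items)
        if not items:
            return np.empty(0)
        return self.model.predict_proba(self.encode(items))

    def save(self, path) -> None:
        node_chain = []
        node = self.node
        while node is not None:
            node_chain.append({"level": node.level, "name": node.name,
                               "center_classes": sorted(node.center_classes)})
            node = node.parent
        payload = {
            "format": "gpspbs-node/1",
            "node_chain": node_chain,
            "m": self.m, "n": self.n,
            "positives": self.positives,
            "weights": self.weights.values.tolist(),
            "matrix": self.matrix.scores.tolist(),
            "model": self.model.to_dict(),
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PredictorNode":
        from .calibration import ThresholdTable

        with open(path) as fh:
            d = json.load(fh)
        node = None
        for entry in reversed(d["node_chain"]):
            node = HierarchyNode(entry["level"], entry["name"], node,
                                 frozenset(entry["center_classes"]))
        out = cls(node, d["m"], d["n"], list(d["positives"]),
                  PositionWeights(np.array(d["weights"])),
                  SubstitutionMatrix(np.array(d["matrix"])),
                  TrainedModel.from_dict(d["model"]))
        if d.get("thresholds"):
            out.thresholds = ThresholdTable.from_dict(d["thresholds"], out.node)
        return out


def _resolve_weights(benchmark: BenchmarkDataset, matrix: SubstitutionMatrix,
                     pwd, seed: int, pwd_kwargs: dict) -> PositionWeights:
    if isinstance(pwd, PositionWeights):
        return pwd
    k = len(benchmark.positives[0].peptide)
    if pwd == "ones":
        return PositionWeights.ones(k)
    if pwd == "plr":
        return fit_plr_weights(benchmark, matrix,
                               l1_strength=pwd_kwargs.get("l1_strength", 1.0))
    if pwd == "full":
        return determine_weights(benchmark, matrix, seed, **pwd_kwargs).weights
    raise ValueError(f"unknown PWD mode {pwd!r}")


def train_node(benchmark: BenchmarkDataset, *,
               matrix: SubstitutionMatrix | None = None,
               pwd="full", pwd_kwargs: dict | None = None,
               dnn_config: DNNConfig | None = None,
               seed: int = 0,
               parent: PredictorNode | None = None,
               fine_tune_kwargs: dict | None = None) -> PredictorNode:
    """Train one hierarchy node end to end.

    ``pwd`` selects how position weights are obtained: ``"full"`` (LASSO fit
    plus hill climb), ``"plr"`` (LASSO only), ``"ones"``, ``"inherit"``
    (reuse the parent's weights), or an explicit :class:`PositionWeights`.
    With ``parent`` given, the network is fine-tuned from the parent model
    instead of trained from scratch.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    pwd_kwargs = dict(pwd_kwargs or {})
    if pwd == "inherit":
        if parent is None:
            raise ValueError("pwd='inherit' requires a parent node")
        weights = parent.weights
    else:
        weights = _resolve_weights(benchmark, matrix, pwd, seed, pwd_kwargs)

    positives = [it.peptide for it in benchmark.positives]
    X = encode_items(benchmark.items, positives, weights, matrix)
    y = benchmark.labels
    if parent is not None:
        model = fine_tune(parent.model, X, y, seed=seed,
                          hierarchy_node=benchmark.node,
                          **(fine_tune_kwargs or {}))
    else:
        config = dnn_config or DNNConfig(seed=seed)
        if config.seed != seed and dnn_config is None:
            config = DNNConfig(seed=seed)
        model = train_dnn(X, y, config, hierarchy_node=benchmark.node)

    item0 = benchmark.positives[0]
    return PredictorNode(benchmark.node, item0.m, item0.n, positives,
                         weights, matrix, model, parent=parent)


def evaluate_node(benchmark: BenchmarkDataset, *, k="auto", seed: int = 0,
                  matrix: SubstitutionMatrix | None = None, pwd="full",
                  pwd_kwargs: dict | None = None,
                  dnn_config: DNNConfig | None = None,
                  fast_loo: bool = True):
    """Cross-validate the full pipeline on a benchmark.

    Under leave-one-out (forced below 30 positives) the position weights
    are, in the default fast mode, optimized once on the whole benchmark
    and held fixed across rounds while the network is refit per round;
    ``fast_loo=False`` re-optimizes the weights in every round instead.
    """
    from .evaluation import cross_validate, select_scheme
    from .pwd import determine_weights

    matrix = matrix or SubstitutionMatrix.blosum62()
    scheme = select_scheme(len(benchmark.positives), k)
    effective_pwd = pwd
    if scheme == "loo" and fast_loo and pwd == "full":
        effective_pwd = determine_weights(benchmark, matrix, seed,
                                          **(pwd_kwargs or {})).weights
    trainer = make_trainer(matrix=matrix, pwd=effective_pwd,
                           pwd_kwargs=pwd_kwargs, dnn_config=dnn_config,
                           seed=seed)
    return cross_validate(benchmark, trainer, k=k, seed=seed)


def make_trainer(*, matrix: SubstitutionMatrix | None = None, pwd="full",
                 pwd_kwargs: dict | None = None,
                 dnn_config: DNNConfig | None = None, seed: int = 0,
                 parent: PredictorNode | None = None,
                 fine_tune_kwargs: dict | None = None):
    """A trainer callable for :func:`gpspbs.evaluation.cross_validate`.

    Maps a training benchmark to a scorer over held-out windows, refitting
    the whole PWD -> PVT -> network pipeline on the training fold.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()

    def trainer(train_benchmark: BenchmarkDataset):
        node = train_node(train_benchmark, matrix=matrix, pwd=pwd,
                          pwd_kwargs=pwd_kwargs, dnn_config=dnn_config,
                          seed=seed, parent=parent,
                          fine_tune_kwargs=fine_tune_kwargs)
        return node.score

    return trainer
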