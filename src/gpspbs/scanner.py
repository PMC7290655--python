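"""End-to-end prediction: scan proteins with a registry of trained predictors.

Every S/T/Y residue matching a selected predictor's center classes is
windowed with that predictor's (m, n), encoded against its positive profile
and weights, scored by its network, and thresholded at the requested
stringency.  One record is emitted per (site, predictor) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calibration import apply_threshold, LEVELS
from .data_model import extract_pbp
from .pipeline import PredictorNode

VALID_LEVELS = (*LEVELS, "All", "all")


@dataclass(frozen=True)
class PredictionRecord:
    protein_id: str
    position: int
    residue: str
    peptide: str
    node: str
    level: str
    score: float
    passed: bool


class PredictorRegistry:
    """Named collection of trained predictor nodes."""

    def __init__(self, predictors: dict[str, PredictorNode] | None = None) -> None:
        self.predictors: dict[str, PredictorNode] = dict(predictors or {})

    def add(self, predictor: PredictorNode, name: str | None = None) -> None:
        self.predictors[name or predictor.node.name] = predictor

    def __getitem__(self, name: str) -> PredictorNode:
        if name not in self.predictors:
            raise KeyError(f"unknown predictor node {name!r}; available: "
                           f"{sorted(self.predictors)}")
        return self.predictors[name]

    def names(self) -> list[str]:
        return sorted(self.predictors)


def scan_protein(protein_id: str, sequence: str, registry: PredictorRegistry,
                 selection=None, level: str = "All") -> list[PredictionRecord]:
    """Score every candidate residue of one protein against selected predictors."""
    if level not in VALID_LEVELS:
        raise ValueError(f"unknown threshold level {level!r}")
    selection = list(selection) if selection is not None else registry.names()
    if not selection:
        raise ValueError("empty predictor selection")
    records: list[PredictionRecord] = []
    for name in selection:
        predictor = registry[name]
        sites = [(i, res) for i, res in enumerate(sequence, start=1)
                 if res in predictor.node.center_classes]
        if not sites:
            continue
        items = [extract_pbp(sequence, pos, predictor.m, predictor.n,
                             protein_id=protein_id) for pos, _ in sites]
        scores = predictor.score(items)
        passed = apply_threshold(scores, predictor.thresholds, level) \
            if level not in ("All", "all") else [True] * len(scores)
        for (pos, res), item, score, ok in zip(sites, items, scores, passed):
            if level in ("All", "all") or ok:
                records.append(PredictionRecord(protein_id, pos, res,
                                                item.peptide, name, level,
                                                float(score), bool(ok)))
    return records


def scan_fasta(sequences: dict[str, str], registry: PredictorRegistry,
               selection=None, level: str = "All") -> pd.DataFrame:
    """Scan a whole FASTA; rows sorted by protein, position, node."""
    records: list[PredictionRecord] = []
    for pid in sequences:
        records.extend(scan_protein(pid, sequences[pid], registry,
                                    selection, level))
    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["protein_id", "position", "residue", "peptide",
                               "node", "level", "score", "passed"])
    return df.sort_values(["protein_id", "position", "node"],
                          kind="stable").reset_index(drop=True)
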