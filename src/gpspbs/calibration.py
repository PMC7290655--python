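"""FPR-based threshold calibration against a random peptide background.

Score cutoffs are anchored to false-positive rates on randomly drawn
background windows rather than to raw probabilities: for each of 20 seeded
draws of 10,000 background PBP windows, the cutoff achieving each target
FPR is located as an empirical quantile, and the per-level cutoffs are
averaged across draws.  Serine/threonine-group predictors use high/medium/
low targets of 2/6/10% FPR; tyrosine-group predictors use 4/9/15%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import HierarchyNode, extract_pbp

PSPT_TARGET_FPRS = {"high": 0.02, "medium": 0.06, "low": 0.10}
PY_TARGET_FPRS = {"high": 0.04, "medium": 0.09, "low": 0.15}

DEFAULT_BACKGROUND_SIZE = 10_000
DEFAULT_REPEATS = 20

LEVELS = ("high", "medium", "low")


def default_target_fprs(node: HierarchyNode) -> dict[str, float]:
    return dict(PY_TARGET_FPRS if node.center_classes == frozenset("Y")
                else PSPT_TARGET_FPRS)


@dataclass
class ThresholdTable:
    """Per-level score cutoffs for one predictor node."""

    node: HierarchyNode
    levels: dict[str, float]
    target_fpr: dict[str, float]
    background_size: int
    repeats: int

    def __post_init__(self) -> None:
        if set(self.levels) != set(LEVELS):
            raise ValueError(f"levels must be exactly {LEVELS}")
        if not (self.levels["high"] >= self.levels["medium"] >= self.levels["low"]):
            raise ValueError("cutoffs must be nested: high >= medium >= low")

    def cutoff(self, level: str) -> float:
        return self.levels[level]

    def to_dict(self) -> dict:
        return {"levels": self.levels, "target_fpr": self.target_fpr,
                "background_size": self.background_size, "repeats": self.repeats}

    @classmethod
    def from_dict(cls, d: dict, node: HierarchyNode) -> "ThresholdTable":
        return cls(node, dict(d["levels"]), dict(d["target_fpr"]),
                   d["background_size"], d["repeats"])


def cutoff_at_fpr(scores: np.ndarray, target: float) -> float:
    """The smallest score c with fraction(scores >= c) <= target.

    With ``target == 0`` (or ties at the maximum exceeding the target) the
    cutoff is placed strictly above the maximum background score.
    """
    scores = np.sort(np.asarray(scores, float))
    n = len(scores)
    unique = np.unique(scores)
    # tail count for each candidate cutoff value
    tail = n - np.searchsorted(scores, unique, side="left")
    ok = tail <= target * n
    if not np.any(ok):
        return float(np.nextafter(scores[-1], np.inf))
    return float(unique[np.argmax(ok)])


def candidate_background_windows(proteome, center_classes, m: int = 10,
                                 n: int = 10) -> list[str]:
    """All PBP(m, n) windows of the proteome centered on the given residues."""
    windows = []
    for pid in sorted(proteome):
        seq = proteome[pid]
        for i, res in enumerate(seq, start=1):
            if res in center_classes:
                windows.append(extract_pbp(seq, i, m, n, protein_id=pid).peptide)
    return windows


def calibrate_thresholds(predictor, background, seed: int = 0, *,
                         background_size: int = DEFAULT_BACKGROUND_SIZE,
                         repeats: int = DEFAULT_REPEATS,
                         target_fprs: dict[str, float] | None = None,
                         ) -> ThresholdTable:
    """Estimate per-level cutoffs from repeated random background draws.

    ``background`` is either a proteome (id -> sequence mapping), from which
    candidate windows of the node's center classes are enumerated, or an
    explicit list of peptide windows.  Each repeat draws ``background_size``
    windows without replacement, locates the per-level quantile cutoffs, and
    the final table averages cutoffs over repeats.
    """
    node = predictor.node
    targets = dict(target_fprs or default_target_fprs(node))
    if isinstance(background, dict):
        windows = candidate_background_windows(background, node.center_classes,
                                               predictor.m, predictor.n)
    else:
        windows = list(background)
    if len(windows) < background_size:
        raise ValueError(
            f"background supplies {len(windows)} candidate windows, "
            f"need at least {background_size}")
    scores = predictor.score(windows)
    rng = np.random.default_rng(seed)
    cutoffs = {level: [] for level in LEVELS}
    for _ in range(repeats):
        draw = scores[rng.choice(len(scores), size=background_size, replace=False)]
        for level in LEVELS:
            cutoffs[level].append(cutoff_at_fpr(draw, targets[level]))
    levels = {level: float(np.mean(cutoffs[level])) for level in LEVELS}
    return ThresholdTable(node, levels, targets, background_size, repeats)


def apply_threshold(scores, table: ThresholdTable | None, level: str) -> np.ndarray:
    """Boolean mask of scores passing the level; ``All`` passes everything."""
    scores = np.asarray(scores, float)
    if level in ("All", "all"):
        return np.ones(len(scores), bool)
    if table is None:
        raise ValueError("a calibrated threshold table is required for "
                         "high/medium/low levels")
    if level not in LEVELS:
        raise ValueError(f"unknown threshold level {level!r}")
    return scores >= table.cutoff(level)
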