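"""Seeded generators of motif-structured benchmarks, proteomes and hierarchies.

Positive windows are drawn from position-specific consensus motifs — e.g.
the 14-3-3-like R-x-R-S-x-pS-x-P pattern, or the SH2-like Y-x-N / Y-x-x-M
patterns — where each constrained offset carries its consensus residue with
an adherence probability q and a background residue otherwise.  Negatives
are drawn purely from the background composition.  Class imbalance is set
by a negative:positive ratio (benchmark imbalances in this problem span
roughly 4 to 200).  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .data_model import (
    BenchmarkDataset,
    HierarchyNode,
    PBPItem,
    PSPT_GROUP,
    PY_GROUP,
)

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20)


@dataclass(frozen=True)
class MotifSpec:
    """A consensus binding motif around a central S, T or Y.

    ``constraints`` maps a window offset (negative = upstream, positive =
    downstream, 0 excluded) to a pair (residue set, adherence probability q).
    """

    name: str
    center_class: str
    constraints: dict = field(default_factory=dict)
    background_frequencies: np.ndarray = field(
        default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        if self.center_class not in "STY" or len(self.center_class) != 1:
            raise ValueError("center_class must be one of S, T, Y")
        for offset, (residues, q) in self.constraints.items():
            if offset == 0:
                raise ValueError("offset 0 is the fixed center residue")
            if not 0 <= q <= 1:
                raise ValueError(f"adherence probability {q} outside [0, 1]")
            if q > 0 and not set(residues):
                raise ValueError(f"offset {offset}: empty residue set with q > 0")
        bg = np.asarray(self.background_frequencies, float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background_frequencies must be 20 probabilities summing to 1")
        object.__setattr__(self, "background_frequencies", bg)

    def extend(self, name: str, extra_constraints: dict) -> "MotifSpec":
        """A child motif: this motif plus additional constraints."""
        merged = {**self.constraints, **extra_constraints}
        return MotifSpec(name, self.center_class, merged,
                         self.background_frequencies.copy())

    @property
    def group(self) -> HierarchyNode:
        return PY_GROUP if self.center_class == "Y" else PSPT_GROUP


def motif_14_3_3(q: float = 0.9) -> MotifSpec:
    """A 14-3-3-like mode-1 motif, R-x-R-S-x-pS-x-P around the central pS."""
    return MotifSpec("14-3-3-like", "S", {
        -5: ("R", 0.6 * q), -3: ("R", q), -2: ("S", 0.6 * q), +2: ("P", q)})


def motif_sh2_grb2(q: float = 0.9) -> MotifSpec:
    """A GRB2-SH2-like Y-x-N motif around the central pY."""
    return MotifSpec("SH2-GRB2-like", "Y", {+2: ("N", q)})


def motif_sh2_pik3r1(q: float = 0.9) -> MotifSpec:
    """A PIK3R1-SH2-like Y-x-x-M motif around the central pY."""
    return MotifSpec("SH2-PIK3R1-like", "Y", {+3: ("M", q)})


def _sample_windows(spec: MotifSpec, count: int, m: int, n: int,
                    rng: np.random.Generator, constrained: bool) -> list[str]:
    k = m + 1 + n
    aa = np.array(list(AMINO_ACIDS))
    codes = rng.choice(20, size=(count, k), p=spec.background_frequencies)
    windows = aa[codes]
    windows[:, m] = spec.center_class
    if constrained:
        for offset, (residues, q) in spec.constraints.items():
            j = m + offset
            if not 0 <= j < k:
                continue
            residues = list(residues)
            hit = rng.random(count) < q
            picks = rng.choice(len(residues), size=count)
            windows[hit, j] = np.array(residues)[picks[hit]]
    return ["".join(row) for row in windows]


def generate_benchmark(spec: MotifSpec, n_pos: int, neg_ratio: float,
                       m: int = 10, n: int = 10, seed: int = 0,
                       node: HierarchyNode | None = None) -> BenchmarkDataset:
    """A seeded benchmark: motif-drawn positives, background-drawn negatives.

    De-duplication at the peptide level may leave fewer than ``n_pos``
    positives; the actual counts are whatever survives, keeping the draw a
    pure function of the seed.
    """
    if n_pos < 1 or neg_ratio <= 0:
        raise ValueError("n_pos must be >= 1 and neg_ratio > 0")
    rng = np.random.default_rng(seed)
    node = node or spec.group
    n_neg = int(round(n_pos * neg_ratio))
    pos_windows = _sample_windows(spec, n_pos, m, n, rng, constrained=True)
    neg_windows = _sample_windows(spec, n_neg, m, n, rng, constrained=False)

    seen: set[str] = set()
    positives, negatives = [], []
    for i, pep in enumerate(pos_windows):
        if pep not in seen:
            seen.add(pep)
            positives.append(PBPItem(f"SYN_{spec.name}_P{i}", m + 1,
                                     spec.center_class, m, n, pep))
    for i, pep in enumerate(neg_windows):
        if pep not in seen:
            seen.add(pep)
            negatives.append(PBPItem(f"SYN_{spec.name}_N{i}", m + 1,
                                     spec.center_class, m, n, pep))
    return BenchmarkDataset(node, positives, negatives)


@dataclass
class SyntheticHierarchy:
    """A group motif refined into family and cluster motifs.

    Children add constraints on top of their parent's, mirroring how binding
    specificity narrows from a domain group down to a single domain.
    """

    group_spec: MotifSpec
    family_specs: dict = field(default_factory=dict)
    cluster_specs: dict = field(default_factory=dict)  # name -> (family, spec)
    group_node: HierarchyNode = None
    family_nodes: dict = field(default_factory=dict)
    cluster_nodes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group_node = self.group_spec.group
        for fam, spec in self.family_specs.items():
            if not set(self.group_spec.constraints) <= set(spec.constraints):
                raise ValueError(f"family {fam} drops group constraints")
            self.family_nodes[fam] = HierarchyNode("family", fam, self.group_node)
        for name, (fam, spec) in self.cluster_specs.items():
            if not set(self.family_specs[fam].constraints) <= set(spec.constraints):
                raise ValueError(f"cluster {name} drops family constraints")
            self.cluster_nodes[name] = HierarchyNode("cluster", name,
                                                     self.family_nodes[fam])


def default_hierarchy(q: float = 0.9) -> SyntheticHierarchy:
    """A small pS/pT hierarchy: group motif, one family, one cluster."""
    group = MotifSpec("pSpT-like", "S", {-3: ("R", q)})
    family = group.extend("14-3-3-like", {+2: ("P", q)})
    cluster = family.extend("YWHAZ-like", {-2: ("S", q)})
    return SyntheticHierarchy(group, {"14-3-3-like": family},
                              {"YWHAZ-like": ("14-3-3-like", cluster)})


def generate_proteome(n_proteins: int, mean_length: int = 400,
                      planted_sites=(), seed: int = 0,
                      min_length: int = 50) -> tuple[dict[str, str], pd.DataFrame]:
    """Background-composition proteins with motif instances planted at
    recorded positions; returns (id -> sequence, truth table).

    ``planted_sites`` is a list of (MotifSpec, count) pairs.  Plant positions
    are chosen away from the termini so the full window fits.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    lengths = np.maximum(min_length, rng.poisson(mean_length, size=n_proteins))
    sequences = {
        f"SYNPROT{i:04d}": "".join(aa[rng.choice(20, size=int(L),
                                                 p=UNIFORM_BACKGROUND)])
        for i, L in enumerate(lengths)
    }
    ids = sorted(sequences)
    truth_rows = []
    m = n = 10
    for spec, count in planted_sites:
        total_slots = sum(max(0, len(sequences[pid]) - 2 * m) for pid in ids)
        if count > total_slots:
            raise ValueError(f"cannot plant {count} sites of {spec.name}: "
                             f"only {total_slots} interior positions available")
        planted = 0
        guard = 0
        while planted < count:
            guard += 1
            if guard > 100 * count + 1000:
                raise ValueError(f"failed to plant {count} sites of {spec.name}")
            pid = ids[int(rng.integers(len(ids)))]
            seq = sequences[pid]
            if len(seq) <= 2 * m:
                continue
            pos = int(rng.integers(m + 1, len(seq) - n + 1))  # 1-based
            if any(r["protein_id"] == pid and abs(r["position"] - pos) <= m + n
                   for r in truth_rows):
                continue
            window = _sample_windows(spec, 1, m, n, rng, constrained=True)[0]
            sequences[pid] = seq[:pos - 1 - m] + window + seq[pos + n:]
            truth_rows.append({"protein_id": pid, "position": pos,
                               "residue": spec.center_class, "motif": spec.name})
            planted += 1
    truth = pd.DataFrame(truth_rows,
                         columns=["protein_id", "position", "residue", "motif"])
    return sequences, truth


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sequences):
            fh.write(f">{pid}\n")
            seq = sequences[pid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
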