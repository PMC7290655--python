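"""Peptide windows, the PPBD hierarchy, and benchmark construction.

A candidate binding phosphosite is represented by a fixed window PBP(m, n):
the central S/T/Y residue with m residues upstream and n downstream, padded
with ``*`` where the window overruns a protein terminus.  Benchmarks pair the
annotated (positive) windows of a hierarchy node with the remaining S/T/Y
windows of the same proteins as negatives, de-duplicated at the peptide level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .alphabet import PAD, sanitize_residue

CENTER_RESIDUES = frozenset("STY")


class SiteError(ValueError):
    """A site annotation that does not match its protein sequence."""


@dataclass(frozen=True)
class PBPItem:
    """A PBP(m, n) peptide window around one candidate S/T/Y site.

    ``*`` marks terminal padding; since non-standard residues (U, B, Z, X,
    ...) also map to ``*`` to keep the 21-symbol alphabet, the symbol may
    occasionally appear in the interior of a window.
    """

    protein_id: str
    position: int  # 1-based position of the center residue
    center_residue: str
    m: int
    n: int
    peptide: str

    def __post_init__(self) -> None:
        if len(self.peptide) != self.m + 1 + self.n:
            raise ValueError(
                f"peptide length {len(self.peptide)} != m+1+n = {self.m + 1 + self.n}")
        if self.peptide[self.m] != self.center_residue:
            raise ValueError("window center does not match the annotated residue")


@dataclass(frozen=True)
class HierarchyNode:
    """One node of the PPBD classification: group, family, or single-PPBD cluster."""

    level: str
    name: str
    parent: "HierarchyNode | None" = None
    center_classes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.level not in ("group", "family", "cluster"):
            raise ValueError(f"unknown hierarchy level {self.level!r}")
        if self.level == "group" and self.parent is not None:
            raise ValueError("a group node has no parent")
        if self.level == "family" and (self.parent is None or self.parent.level != "group"):
            raise ValueError("a family's parent must be a group")
        if self.level == "cluster" and (self.parent is None or self.parent.level != "family"):
            raise ValueError("a cluster's parent must be a family")
        cc = frozenset(self.center_classes) or (
            self.parent.center_classes if self.parent else frozenset())
        if not cc <= CENTER_RESIDUES:
            raise ValueError(f"center classes must be a subset of S/T/Y, got {set(cc)}")
        object.__setattr__(self, "center_classes", cc)

    @property
    def group(self) -> "HierarchyNode":
        node = self
        while node.parent is not None:
            node = node.parent
        return node


#: The two benchmark groups: serine/threonine readers and tyrosine readers.
PSPT_GROUP = HierarchyNode("group", "pS/pT", center_classes=frozenset("ST"))
PY_GROUP = HierarchyNode("group", "pY", center_classes=frozenset("Y"))

#: Minimum number of known binding sites for a cluster to get its own model.
MIN_CLUSTER_POSITIVES = 3


def admissible_for_training(node: HierarchyNode, n_positives: int) -> bool:
    if node.level == "cluster":
        return n_positives >= MIN_CLUSTER_POSITIVES
    return n_positives >= 1


def extract_pbp(sequence: str, position: int, m: int = 10, n: int = 10,
                protein_id: str = "", allowed_centers: Iterable[str] | None = None,
                ) -> PBPItem:
    """Cut the PBP(m, n) window centered on a 1-based sequence position.

    Windows overrunning either terminus are padded with ``*``; non-standard
    residues are likewise mapped to ``*`` so the peptide stays within the
    21-symbol alphabet.
    """
    if not 1 <= position <= len(sequence):
        raise SiteError(
            f"position {position} out of range for {protein_id or 'sequence'} "
            f"of length {len(sequence)}")
    center = sanitize_residue(sequence[position - 1])
    if allowed_centers is not None and center not in set(allowed_centers):
        raise SiteError(
            f"residue {sequence[position - 1]!r} at {protein_id}:{position} "
            f"is not one of {sorted(allowed_centers)}")
    start, stop = position - 1 - m, position + n
    left_pad = max(0, -start)
    right_pad = max(0, stop - len(sequence))
    core = sequence[max(0, start):min(len(sequence), stop)]
    peptide = PAD * left_pad + "".join(sanitize_residue(c) for c in core) + PAD * right_pad
    return PBPItem(protein_id, position, center, m, n, peptide)


@dataclass
class BenchmarkDataset:
    """Labeled positive and negative windows for one hierarchy node."""

    node: HierarchyNode
    positives: list[PBPItem]
    negatives: list[PBPItem]

    def __post_init__(self) -> None:
        pos = {p.peptide for p in self.positives}
        neg = {p.peptide for p in self.negatives}
        if len(pos) != len(self.positives):
            raise ValueError("duplicate peptides within positives")
        if len(neg) != len(self.negatives):
            raise ValueError("duplicate peptides within negatives")
        if pos & neg:
            raise ValueError("a peptide appears in both positives and negatives")
        for item in self.positives + self.negatives:
            if item.center_residue not in self.node.center_classes:
                raise ValueError(
                    f"center {item.center_residue!r} outside node classes "
                    f"{sorted(self.node.center_classes)}")

    @property
    def items(self) -> list[PBPItem]:
        return self.positives + self.negatives

    @property
    def labels(self):
        import numpy as np

        return np.r_[np.ones(len(self.positives), int), np.zeros(len(self.negatives), int)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": it.protein_id, "position": it.position,
             "residue": it.center_residue, "peptide": it.peptide, "label": lab}
            for lab, items in ((1, self.positives), (0, self.negatives))
            for it in items
        ]
        return pd.DataFrame(rows, columns=["protein_id", "position", "residue",
                                           "peptide", "label"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, node: HierarchyNode) -> "BenchmarkDataset":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        pos, neg = [], []
        for row in df.itertuples(index=False):
            k = (len(row.peptide) - 1) // 2
            item = PBPItem(row.protein_id, int(row.position), row.residue,
                           k, len(row.peptide) - 1 - k, row.peptide)
            (pos if row.label else neg).append(item)
        return cls(node, pos, neg)


def _dedup(items: Iterable[PBPItem], exclude: set[str] | None = None) -> list[PBPItem]:
    """Keep the first occurrence of each peptide string, in input order."""
    seen: set[str] = set(exclude or ())
    out = []
    for it in items:
        if it.peptide not in seen:
            seen.add(it.peptide)
            out.append(it)
    return out


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines allowed) as an id -> sequence map."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_site_table(path) -> pd.DataFrame:
    """Site annotations as TSV with columns protein_id, position, residue[, node]."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "residue"}
    if not required <= set(df.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    return df


def build_benchmark(proteins: Mapping[str, str], positive_sites: pd.DataFrame,
                    node: HierarchyNode, m: int = 10, n: int = 10,
                    ) -> BenchmarkDataset:
    """Assemble the benchmark for a node from sequences and annotated sites.

    Positives are the windows of the annotated sites; negatives are the
    windows of every other residue of the node's center classes in the same
    proteins.  Both sides are de-duplicated at the peptide-string level and
    any negative identical to a positive is dropped.
    """
    if len(positive_sites) == 0:
        raise ValueError("no positive sites supplied")
    positive_keys: set[tuple[str, int]] = set()
    positives = []
    for row in positive_sites.itertuples(index=False):
        pid, pos = str(row.protein_id), int(row.position)
        if pid not in proteins:
            raise SiteError(f"protein {pid} not present in the sequence input")
        seq = proteins[pid]
        if not 1 <= pos <= len(seq):
            raise SiteError(f"position {pos} out of range for {pid} (length {len(seq)})")
        if seq[pos - 1] != row.residue:
            raise SiteError(
                f"annotated residue {row.residue!r} at {pid}:{pos} "
                f"does not match sequence residue {seq[pos - 1]!r}")
        if row.residue not in node.center_classes:
            raise SiteError(
                f"site {pid}:{pos} residue {row.residue!r} outside node "
                f"classes {sorted(node.center_classes)}")
        positive_keys.add((pid, pos))
        positives.append(extract_pbp(seq, pos, m, n, protein_id=pid))
    positives = _dedup(positives)
    pos_peptides = {p.peptide for p in positives}

    negatives = []
    for pid in sorted({str(r.protein_id) for r in positive_sites.itertuples(index=False)}):
        seq = proteins[pid]
        for i, residue in enumerate(seq, start=1):
            if residue in node.center_classes and (pid, i) not in positive_keys:
                negatives.append(extract_pbp(seq, i, m, n, protein_id=pid))
    negatives = _dedup(negatives, exclude=pos_peptides)
    return BenchmarkDataset(node, positives, negatives)
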