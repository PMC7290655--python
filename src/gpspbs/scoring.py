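"""Substitution-matrix machinery and the group-based similarity score.

The group-based prediction score of a query window ``A`` against a positive
set ``P_1..P_N`` of equal-length windows is

    S = (1/N) * sum_j ( sum_i M(A_j, P_ij) ) * W_j

where ``M`` is a residue substitution matrix (BLOSUM62 by default, extended
with its conventional ``*`` row/column) and ``W_j`` a per-position weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    ALPHABET,
    ALPHABET_SIZE,
    PAIR_INDEX,
    N_PAIRS,
    encode_peptides,
)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 21x21 residue similarity table over :data:`ALPHABET`."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (ALPHABET_SIZE, ALPHABET_SIZE):
            raise ValueError(f"expected a {ALPHABET_SIZE}x{ALPHABET_SIZE} table, got {s.shape}")
        if not np.allclose(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", s)

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """BLOSUM62 restricted to the 20 standard residues plus ``*``."""
        from Bio.Align import substitution_matrices

        full = substitution_matrices.load("BLOSUM62")
        s = np.empty((ALPHABET_SIZE, ALPHABET_SIZE))
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                s[i, j] = full[a, b]
        return cls(s)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.scores[ALPHABET.index(a), ALPHABET.index(b)])

    def pair_scores(self) -> np.ndarray:
        """The 231-vector of scores indexed by canonical unordered pair."""
        out = np.empty(N_PAIRS)
        for i in range(ALPHABET_SIZE):
            for j in range(i, ALPHABET_SIZE):
                out[PAIR_INDEX[i, j]] = self.scores[i, j]
        return out

    @classmethod
    def from_file(cls, path) -> "SubstitutionMatrix":
        """Read a matrix in the NCBI text format (header row of symbols)."""
        rows: dict[str, dict[str, float]] = {}
        header: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line or line.lstrip().startswith("#"):
                    continue
                fields = line.split()
                if header is None:
                    header = fields
                    continue
                sym, vals = fields[0], fields[1:]
                rows[sym] = {h: float(v) for h, v in zip(header, vals)}
        if header is None:
            raise ValueError(f"no matrix found in {path}")
        missing = [c for c in ALPHABET if c not in rows]
        if missing:
            raise ValueError(f"matrix lacks rows for symbols: {missing}")
        s = np.array([[rows[a][b] for b in ALPHABET] for a in ALPHABET])
        return cls(s)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("   " + "  ".join(ALPHABET) + "\n")
            for i, a in enumerate(ALPHABET):
                vals = " ".join(f"{int(v):3d}" if float(v).is_integer() else f"{v:5.1f}"
                                for v in self.scores[i])
                fh.write(f"{a} {vals}\n")


@dataclass(frozen=True)
class PositionWeights:
    """Per-position weights ``W_j`` over the K window positions."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("weights must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "values", v)

    @classmethod
    def ones(cls, k: int) -> "PositionWeights":
        return cls(np.ones(k))

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path, center: int | None = None) -> None:
        k = len(self.values)
        if center is None:
            center = k // 2
        with open(path, "w") as fh:
            fh.write("position\toffset\tweight\n")
            for j, w in enumerate(self.values):
                fh.write(f"{j}\t{j - center}\t{w:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "PositionWeights":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["weight"].to_numpy(float))


class PositiveProfile:
    """Per-position residue counts of a positive peptide set.

    The group-based score and the pair-similarity encoding both depend on the
    positives only through the count table ``C[j, b]`` = number of positives
    carrying residue ``b`` at position ``j``, which makes scoring independent
    of the positive-set size.
    """

    def __init__(self, peptides) -> None:
        codes = encode_peptides([p.peptide if hasattr(p, "peptide") else p
                                 for p in peptides])
        self.n_positives, self.k = codes.shape
        counts = np.zeros((self.k, ALPHABET_SIZE))
        for j in range(self.k):
            counts[j] = np.bincount(codes[:, j], minlength=ALPHABET_SIZE)
        self.counts = counts

    def per_position_scores(self, query_codes: np.ndarray,
                            matrix: SubstitutionMatrix) -> np.ndarray:
        """Mean substitution score per position, shape (n_queries, K).

        Entry (q, j) is ``(1/N) * sum_i M(A_qj, P_ij)``.
        """
        q = np.atleast_2d(query_codes)
        if q.shape[1] != self.k:
            raise ValueError(f"query length {q.shape[1]} != positive length {self.k}")
        # M[q] has shape (B, K, 21); contract against counts over residues.
        return np.einsum("bkc,kc->bk", matrix.scores[q], self.counts) / self.n_positives


def _as_peptide_list(positives) -> list:
    positives = list(positives)
    if not positives:
        raise ValueError("positive set is empty")
    return positives


def per_position_scores(query, positives, matrix: SubstitutionMatrix) -> np.ndarray:
    """Vector s with s_j the mean substitution score between the query and all
    positives at position j; the group score is ``sum_j s_j * W_j``."""
    profile = PositiveProfile(_as_peptide_list(positives))
    q = encode_peptides(query.peptide if hasattr(query, "peptide") else query)
    return profile.per_position_scores(q, matrix)[0]


def similarity_score(query, positives, weights: PositionWeights,
                     matrix: SubstitutionMatrix) -> float:
    """The group-based similarity score S of one query against the positive set.

    The query is not excluded from the positive set when it happens to belong
    to it; leave-one-out handling is the evaluator's job.
    """
    s = per_position_scores(query, positives, matrix)
    if len(weights) != len(s):
        raise ValueError(f"weights length {len(weights)} != window length {len(s)}")
    return float(s @ weights.values)
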