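"""Peptide-to-vector transformation (PVT).

The scalar group-based score is expanded into a 231-dimensional vector of
unordered residue-pair average similarities.  For a query window ``A`` and a
positive set ``P``, each unordered pair {a, b} receives

    S_ab = sum_j D_j(ab) * M(a, b) * W_j  /  sum_j D_j(ab)

where ``D_j(ab)`` counts, at position j, the pairings between the query
residue and the positive-set residues that realize {a, b}.  The denominator
is pair-specific, making S_ab a position-weight average of M(a, b) over the
positions where the pair occurs; pairs never realized encode as 0.  Laid out
in the canonical pair order this is the fixed-width input of the classifier.
"""

from __future__ import annotations

import numpy as np

from .alphabet import ALPHABET_SIZE, N_PAIRS, PAIR_INDEX, PAIR_NAMES, encode_peptides
from .scoring import PositionWeights, PositiveProfile, SubstitutionMatrix

_CHUNK = 2048


def encode_matrix(query_codes: np.ndarray, profile: PositiveProfile,
                  weights: PositionWeights, matrix: SubstitutionMatrix,
                  ) -> np.ndarray:
    """PVT-encode a batch of queries; returns an (n_queries, 231) array.

    Because every positive with residue b at position j contributes the same
    pair {A_j, b}, the encoding depends on the positives only through the
    profile counts, so each query costs O(K * 21) regardless of the size of
    the positive set.
    """
    q = np.atleast_2d(query_codes)
    k = profile.k
    if q.shape[1] != k:
        raise ValueError(f"query length {q.shape[1]} != positive length {k}")
    if len(weights) != k:
        raise ValueError(f"weights length {len(weights)} != window length {k}")
    w = weights.values
    counts = profile.counts  # (K, 21)
    wcounts = counts * w[:, None]
    pair_scores = matrix.pair_scores()

    out = np.empty((q.shape[0], N_PAIRS))
    for lo in range(0, q.shape[0], _CHUNK):
        chunk = q[lo:lo + _CHUNK]
        b = chunk.shape[0]
        # pair index of {query residue at j, residue b} for all (query, j, b)
        pi = PAIR_INDEX[chunk].astype(np.int64)  # (b, K, 21)
        flat = (np.arange(b)[:, None, None] * N_PAIRS + pi).ravel()
        den = np.bincount(flat, weights=np.broadcast_to(counts, pi.shape).ravel(),
                          minlength=b * N_PAIRS).reshape(b, N_PAIRS)
        num = np.bincount(flat, weights=np.broadcast_to(wcounts, pi.shape).ravel(),
                          minlength=b * N_PAIRS).reshape(b, N_PAIRS)
        vals = np.zeros_like(num)
        realized = den > 0
        vals[realized] = num[realized] / den[realized]
        out[lo:lo + _CHUNK] = vals * pair_scores
    return out


def encode_pvt(query, positives, weights: PositionWeights,
               matrix: SubstitutionMatrix) -> np.ndarray:
    """The 231-vector encoding of one query against a positive set."""
    positives = list(positives)
    if not positives:
        raise ValueError("positive set is empty")
    profile = PositiveProfile(positives)
    q = encode_peptides(query.peptide if hasattr(query, "peptide") else query)
    return encode_matrix(q, profile, weights, matrix)[0]


def encode_items(items, positives, weights: PositionWeights,
                 matrix: SubstitutionMatrix) -> np.ndarray:
    """PVT-encode a list of peptide windows against one positive set."""
    positives = list(positives)
    if not positives:
        raise ValueError("positive set is empty")
    profile = PositiveProfile(positives)
    codes = encode_peptides([it.peptide if hasattr(it, "peptide") else it
                             for it in items])
    return encode_matrix(codes, profile, weights, matrix)


def to_frame(vectors: np.ndarray):
    """Encoded vectors as a DataFrame with the 231 pair names as columns."""
    import pandas as pd

    return pd.DataFrame(np.atleast_2d(vectors), columns=PAIR_NAMES)
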