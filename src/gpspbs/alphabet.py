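"""The 21-letter pseudo-amino-acid alphabet and unordered residue-pair indexing.

Peptide windows are written over the 20 standard one-letter amino acid codes
plus ``*``, the terminal-padding symbol.  The alphabet is kept in alphabetical
order with ``*`` last, so the 231 unordered symbol pairs enumerate as
(A,A), (A,C), (A,D), ..., (*,*).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "*"
ALPHABET = AMINO_ACIDS + PAD
ALPHABET_SIZE = len(ALPHABET)  # 21
N_PAIRS = ALPHABET_SIZE * (ALPHABET_SIZE + 1) // 2  # 231

_CODE = {c: i for i, c in enumerate(ALPHABET)}

# Non-standard residue codes collapse onto the pad symbol so that every
# sequence maps into the fixed 21-symbol alphabet.
_LOOKUP = np.full(128, _CODE[PAD], dtype=np.int8)
for _c, _i in _CODE.items():
    _LOOKUP[ord(_c)] = _i
    _LOOKUP[ord(_c.lower())] = _i


def sanitize_residue(residue: str) -> str:
    """Map a single character onto the 21-symbol alphabet."""
    r = residue.upper()
    return r if r in _CODE else PAD


def encode_peptides(peptides) -> np.ndarray:
    """Encode peptide strings as an (n, K) int8 array of alphabet codes.

    Accepts a single string or an iterable of equal-length strings.
    Characters outside the alphabet (B, J, O, U, X, Z, ...) code as ``*``.
    """
    if isinstance(peptides, str):
        peptides = [peptides]
    else:
        peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides to encode")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError(f"peptides differ in length: {sorted(lengths)}")
    buf = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    return _LOOKUP[buf].reshape(len(peptides), lengths.pop())


def decode_peptide(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _build_pair_index() -> tuple[np.ndarray, list[str]]:
    index = np.empty((ALPHABET_SIZE, ALPHABET_SIZE), dtype=np.int16)
    names: list[str] = []
    k = 0
    for i in range(ALPHABET_SIZE):
        for j in range(i, ALPHABET_SIZE):
            index[i, j] = k
            index[j, i] = k
            names.append(ALPHABET[i] + ALPHABET[j])
            k += 1
    return index, names


#: (21, 21) symmetric table mapping a pair of alphabet codes to its
#: canonical index in 0..230.
PAIR_INDEX, PAIR_NAMES = _build_pair_index()
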