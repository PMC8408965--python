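"""Low-level DNA sequence codecs shared across the package.

Sequences are encoded as int8 arrays with A,C,G,T -> 0..3 and any other
letter (N, IUPAC ambiguity) -> 4.  Fixed-length oligo sets are held as
(n_oligos, oligo_length) matrices so that k-mer extraction, reverse
complementing and PWM scoring are plain vectorized array operations.

k-mers are packed into int64 codes base-4 (first letter most significant),
so k <= 31 is representable; the pipeline never goes past k = 15.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(COMPLEMENT)[::-1]


def canonical(word: str) -> str:
    """Lexicographically smaller of a word and its reverse complement."""
    rc = reverse_complement(word)
    return word if word <= rc else rc


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def encode_matrix(seqs) -> np.ndarray:
    """Encode an iterable of equal-length strings as an (n, L) int8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    joined = "".join(s.upper() for s in seqs)
    flat = _ENC[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    n = len(seqs)
    length = len(seqs[0])
    if flat.size != n * length:
        raise ValueError("sequences of unequal length cannot form a matrix")
    return flat.reshape(n, length)


def word_to_code(word: str) -> int:
    code = 0
    for ch in word.upper():
        b = _ENC[ord(ch)]
        if b == 4:
            raise ValueError(f"cannot encode ambiguous word {word!r}")
        code = code * 4 + int(b)
    return code


def code_to_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def window_codes(mat: np.ndarray, k: int):
    """Forward-strand k-mer codes for every window of every row.

    Returns (codes, valid) of shape (n, L-k+1); windows containing a
    non-ACGT base are flagged invalid (their code is meaningless).
    """
    n, length = mat.shape
    if k > length:
        raise ValueError(f"k={k} exceeds sequence length {length}")
    w = length - k + 1
    codes = np.zeros((n, w), dtype=np.int64)
    invalid = np.zeros((n, w), dtype=bool)
    for t in range(k):
        col = mat[:, t : t + w]
        codes = codes * 4 + np.where(col == 4, 0, col)
        invalid |= col == 4
    return codes, ~invalid


def canonical_window_codes(mat: np.ndarray, k: int):
    """Canonical (strand-symmetric) k-mer codes for every window.

    The canonical code of a window is min(code, code of its reverse
    complement); identical for a window read off either strand.
    """
    fwd, valid = window_codes(mat, k)
    # rc of window j in a row equals window (w-1-j) of the rc'd row
    rcmat = np.where(mat == 4, 4, 3 - mat)[:, ::-1]
    rev, _ = window_codes(rcmat, k)
    rc_aligned = rev[:, ::-1]
    return np.minimum(fwd, rc_aligned), valid
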