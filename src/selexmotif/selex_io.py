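"""SELEX round libraries and double-stranded k-mer counting.

A round library is a set of fixed-length oligos; round index 0 is the
unselected starting pool.  k-mers are counted per window position with the
word identified with its canonical form (the lexicographically smaller of
the word and its reverse complement), so an occurrence read off either
strand increments one shared counter.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from ._seq import canonical, canonical_window_codes, code_to_word, encode_matrix, word_to_code

logger = logging.getLogger(__name__)


@dataclass
class SelexRound:
    """One HT-SELEX round: a fixed-length oligo library."""

    round_index: int
    oligos: list[str]
    oligo_length: int
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")

    @property
    def n_oligos(self) -> int:
        return len(self.oligos)

    @property
    def matrix(self) -> np.ndarray:
        """(n_oligos, oligo_length) int8 encoding, built lazily."""
        if self._matrix is None:
            self._matrix = encode_matrix(self.oligos)
        return self._matrix


@dataclass
class KmerTable:
    """Canonical k-mer counts over all window positions of one round."""

    k: int
    counts: dict[int, int]  # canonical code -> count
    total_positions: int

    def count(self, word: str) -> int:
        return self.counts.get(word_to_code(canonical(word)), 0)

    def frequency(self, word: str) -> float:
        if len(word) != self.k:
            raise ValueError(f"word length {len(word)} != table k {self.k}")
        if self.total_positions == 0:
            return 0.0
        return self.count(word) / self.total_positions

    def words(self, min_count: int = 0):
        """Canonical words (as strings) with count >= min_count."""
        return [
            code_to_word(c, self.k)
            for c, n in self.counts.items()
            if n >= min_count
        ]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_round(path, format: str = "fasta", round_index: int = 0,
               max_deviant_fraction: float = 0.05) -> SelexRound:
    """Read a round library from FASTA or FASTQ (gzip-transparent).

    Records whose length deviates from the modal length are dropped (with a
    logged count); if they exceed ``max_deviant_fraction`` of the file the
    library is rejected.  Qualities in FASTQ are ignored.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with _open_text(path) as fh:
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(fh, format)]
    if not seqs:
        raise ValueError(f"no records in {path}")
    lengths = np.array([len(s) for s in seqs])
    modal = int(np.bincount(lengths).argmax())
    keep = [s for s in seqs if len(s) == modal]
    dropped = len(seqs) - len(keep)
    if dropped:
        if dropped / len(seqs) > max_deviant_fraction:
            raise ValueError(
                f"{dropped}/{len(seqs)} records deviate from modal length "
                f"{modal}; exceeds tolerance {max_deviant_fraction}"
            )
        logger.warning("dropped %d/%d records of deviant length (modal %d)",
                       dropped, len(seqs), modal)
    return SelexRound(round_index=round_index, oligos=keep, oligo_length=modal)


def count_kmers(round: SelexRound, k: int) -> KmerTable:
    """Count canonical k-mers over every window position of every oligo.

    Each window position contributes once (to the canonical form of the
    word it spells); windows containing N are skipped.
    """
    if not 1 <= k <= round.oligo_length:
        raise ValueError(f"k={k} outside [1, {round.oligo_length}]")
    codes, valid = canonical_window_codes(round.matrix, k)
    total = codes.size
    flat = codes[valid]
    uniq, cnt = np.unique(flat, return_counts=True)
    return KmerTable(
        k=k,
        counts=dict(zip(uniq.tolist(), cnt.tolist())),
        total_positions=total,
    )


def kmer_frequency(table: KmerTable, word: str) -> float:
    """Canonical frequency of a word: count(canonical(word)) / positions."""
    return table.frequency(word)
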