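"""Position weight matrices and FIMO-style scanning.

A :class:`Pwm` is a per-position probability distribution over A/C/G/T.
Scanning converts the PWM to a log-odds score matrix against a 0-order
background, derives the score threshold corresponding to a match p-value
by exact dynamic programming over the discretized score distribution, and
reports every window (on either strand) at or above the threshold.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import BASES, encode, encode_matrix, reverse_complement

#: default pseudocount added to PWM probabilities before taking logs;
#: CIS-BP matrices contain exact zeros.
LOG_PSEUDOCOUNT = 1e-4

#: default score discretization granularity for the p-value DP, in bits.
SCORE_GRANULARITY = 1e-3

UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class Pwm:
    """A motif as per-position nucleotide probabilities.

    Parameters
    ----------
    name : str
        Identifier.
    matrix : ndarray of shape (width, 4)
        Probabilities over (A, C, G, T); every row sums to 1.
    source : str
        One of ``cisbp``, ``canonical_cluster``, ``noncanonical_cluster``,
        ``planted``.
    """

    name: str
    matrix: np.ndarray
    source: str = "cisbp"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (width >= 1, 4)")
        if (m < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("every PWM column must sum to 1")
        m = m / m.sum(axis=1, keepdims=True)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return replace(self, matrix=self.matrix[::-1, ::-1].copy())

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits."""
        return np.array([column_information(col) for col in self.matrix])


@dataclass(frozen=True)
class MotifMatch:
    """One PWM occurrence in a scanned sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    matched_word: str = field(default="", compare=False)


def column_information(column) -> float:
    """Information content of one probability column, in bits.

    IC = 2 + sum_b p_b log2 p_b, with 0 log 0 := 0; ranges over [0, 2].
    """
    col = np.asarray(column, dtype=float)
    if col.shape != (4,):
        raise ValueError("column must be a length-4 probability vector")
    if not math.isclose(col.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("column must sum to 1")
    nz = col[col > 0]
    return float(2.0 + (nz * np.log2(nz)).sum())


def trim_motif(pwm: Pwm, ic_threshold: float = 0.25) -> Pwm | None:
    """Strip uninformative flanks from a motif.

    Leading and trailing columns with information content below
    ``ic_threshold`` bits are removed, stopping at the first informative
    column from each end; interior columns are never touched.  Returns
    ``None`` when every column is below threshold.
    """
    ic = pwm.information_content()
    keep = np.flatnonzero(ic >= ic_threshold)
    if keep.size == 0:
        return None
    lo, hi = keep[0], keep[-1] + 1
    if lo == 0 and hi == pwm.width:
        return pwm
    return replace(pwm, matrix=pwm.matrix[lo:hi].copy())


def log_odds_matrix(
    pwm: Pwm, background=UNIFORM, pseudocount: float = LOG_PSEUDOCOUNT
) -> np.ndarray:
    """Log-odds scores (bits) of the PWM against a 0-order background."""
    bg = np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background must be strictly positive")
    bg = bg / bg.sum()
    p = pwm.matrix + pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    return np.log2(p / bg)


class ScoreDistribution:
    """Exact distribution of a PWM's log-odds score under a 0-order background.

    Scores are discretized to integer multiples of ``granularity`` bits and
    the distribution of the width-position sum is built by dynamic
    programming, exactly as used to translate a match p-value into a score
    threshold.  The same integer score matrix is used for scanning, so DP
    tail counts agree exactly with exhaustive word enumeration.
    """

    def __init__(self, pwm: Pwm, background=UNIFORM,
                 granularity: float = SCORE_GRANULARITY,
                 pseudocount: float = LOG_PSEUDOCOUNT):
        bg = np.asarray(background, dtype=float)
        if (bg <= 0).any():
            raise ValueError("background must be strictly positive")
        bg = bg / bg.sum()
        self.granularity = float(granularity)
        self.background = bg
        lo = log_odds_matrix(pwm, bg, pseudocount)
        self.int_scores = np.rint(lo / granularity).astype(np.int64)

        mins = self.int_scores.min(axis=1)
        self._offset = int(mins.sum())  # lowest achievable total
        span = int((self.int_scores.max(axis=1) - mins).sum())
        pmf = np.zeros(span + 1)
        pmf[0] = 1.0
        used = 0
        for i in range(self.int_scores.shape[0]):
            row = self.int_scores[i] - mins[i]
            step = np.zeros(used + int(row.max()) + 1)
            for b in range(4):
                step[row[b] : row[b] + used + 1] += bg[b] * pmf[: used + 1]
            used += int(row.max())
            pmf[: used + 1] = step
        self.pmf = pmf
        # survival[j] = P(total int score >= offset + j)
        self.survival = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, int_score: int) -> float:
        """P(score >= int_score) for a background-random word."""
        j = int_score - self._offset
        if j <= 0:
            return 1.0
        if j >= self.survival.size:
            return 0.0
        return float(min(self.survival[j], 1.0))

    def threshold_for_pvalue(self, pvalue: float) -> int:
        """Smallest integer score whose tail probability is <= pvalue."""
        if not 0 < pvalue <= 1:
            raise ValueError("pvalue must be in (0, 1]")
        # survival is non-increasing; find first index with survival <= p.
        # If even the best score is too probable, the threshold lands one
        # past the maximum achievable score and nothing matches.
        idx = np.searchsorted(-self.survival, -pvalue, side="left")
        return self._offset + int(idx)

    def score_word(self, word: str) -> int:
        codes = encode(word)
        if (codes == 4).any():
            raise ValueError("cannot score a word containing N")
        return int(self.int_scores[np.arange(len(word)), codes].sum())


def score_threshold_for_pvalue(
    pwm: Pwm, background=UNIFORM, pvalue: float = 1e-4,
    granularity: float = SCORE_GRANULARITY,
) -> float:
    """Log-odds threshold (bits) such that P[score(W) >= t] <= pvalue."""
    dist = ScoreDistribution(pwm, background, granularity)
    return dist.threshold_for_pvalue(pvalue) * dist.granularity


def estimate_background(sequences) -> np.ndarray:
    """0-order base composition of a sequence set, strand-symmetrized."""
    counts = np.ones(4)  # pseudocount keeps degenerate sets scannable
    for seq in sequences:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    sym = (counts + counts[::-1]) / 2
    return sym / sym.sum()


def scan_sequences(
    pwm: Pwm,
    sequences,
    pvalue: float = 1e-4,
    background=None,
    sequence_ids=None,
    granularity: float = SCORE_GRANULARITY,
) -> list[MotifMatch]:
    """Report every window on either strand scoring at or above the
    p-value threshold.

    ``sequences`` is an iterable of DNA strings (N allowed; windows
    containing N are skipped).  ``background`` defaults to the 0-order
    composition of the scanned set itself.  Matches are sorted by
    (sequence_id index, start).
    """
    seqs = list(sequences)
    if sequence_ids is None:
        sequence_ids = [f"seq{i}" for i in range(len(seqs))]
    if background is None:
        background = estimate_background(seqs)
    # strand-symmetrize so +/- windows share one score distribution
    background = np.asarray(background, dtype=float)
    background = (background + background[::-1]) / 2
    dist = ScoreDistribution(pwm, background, granularity)
    thr = dist.threshold_for_pvalue(pvalue)
    w = pwm.width
    fwd = dist.int_scores
    rev = fwd[::-1, ::-1]  # scores the rc of the motif on the forward window

    matches: list[MotifMatch] = []
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1 and seqs:
        groups = [(list(range(len(seqs))), encode_matrix(seqs))]
    else:
        groups = [([i], encode_matrix([s])) for i, s in enumerate(seqs) if len(s) >= w]

    for idx, mat in groups:
        n, length = mat.shape
        if length < w:
            continue
        npos = length - w + 1
        sf = np.zeros((n, npos), dtype=np.int64)
        sr = np.zeros((n, npos), dtype=np.int64)
        bad = np.zeros((n, npos), dtype=bool)
        for t in range(w):
            col = mat[:, t : t + npos]
            safe = np.where(col == 4, 0, col)
            sf += fwd[t][safe]
            sr += rev[t][safe]
            bad |= col == 4
        for strand, scores in (("+", sf), ("-", sr)):
            hit_rows, hit_cols = np.nonzero((scores >= thr) & ~bad)
            for r, c in zip(hit_rows.tolist(), hit_cols.tolist()):
                i = idx[r]
                s = int(scores[r, c])
                matches.append(MotifMatch(
                    sequence_id=sequence_ids[i],
                    start=c, end=c + w, strand=strand,
                    score=s * dist.granularity,
                    pvalue=dist.pvalue(s),
                    matched_word=seqs[i][c : c + w],
                ))
    order = {sid: i for i, sid in enumerate(sequence_ids)}
    matches.sort(key=lambda m: (order[m.sequence_id], m.start, m.strand))
    return matches


# ---------------------------------------------------------------------------
# motif file formats


def read_meme(path_or_handle) -> list[Pwm]:
    """Read motifs from MEME minimal format via Bio.motifs."""
    from Bio import motifs as bio_motifs

    if hasattr(path_or_handle, "read"):
        records = bio_motifs.parse(path_or_handle, "minimal")
    else:
        with open(path_or_handle) as fh:
            records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        mat = np.column_stack([rec.pwm[b] for b in BASES])
        out.append(Pwm(name=rec.name, matrix=mat, source="cisbp"))
    return out


def write_meme(pwms, path_or_handle, background=UNIFORM) -> None:
    """Write motifs in MEME minimal format."""
    bg = np.asarray(background, dtype=float)
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{b} {p:.5f}" for b, p in zip(BASES, bg)) + "\n\n")
    for pwm in pwms:
        buf.write(f"MOTIF {pwm.name}\n")
        buf.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 1000000 E= 0\n"
        )
        for row in pwm.matrix:
            buf.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
        buf.write("\n")
    text = buf.getvalue()
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)


def read_cisbp(path_or_handle, name: str | None = None) -> Pwm:
    """Read one CIS-BP TXT matrix ("Pos A C G T" header, one row per
    position).  Rows that do not sum to 1 are normalized."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
        src_name = name or "cisbp_motif"
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()
        src_name = name or str(path_or_handle)
    rows = []
    for line in lines:
        parts = line.split()
        if not parts or parts[0].lower() == "pos":
            continue
        vals = [float(x) for x in parts[1:5]]
        rows.append(vals)
    if not rows:
        raise ValueError("CIS-BP matrix file contains no data rows")
    mat = np.asarray(rows)
    mat = mat / mat.sum(axis=1, keepdims=True)
    return Pwm(name=src_name, matrix=mat, source="cisbp")
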