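"""The L-mer ledger: counting, entropy and enrichment filters, motif /
non-motif classification, round-over-round and alone-occurrence filters.

The central object is a list of :class:`LmerRecord`, one per canonical
L-mer surviving the minimum-count filter, which the pipeline successively
annotates and prunes:

1. count >= min_count and dinucleotide entropy >= the floor set by the
   canonical-motif matches (removes poly-A/poly-C style artifacts);
2. enrichment P_R/P0 versus the round #0 background model, ranked;
3. words linked to a canonical-motif match (substring/superstring of a
   match interval in at least one oligo) are "motif" L-mers, everything
   ranked below the least-enriched motif L-mer is discarded;
4. non-motif words must show round-over-round enrichment >= 1 across all
   consecutive round pairs and must occur "alone" (without any motif
   L-mer) in at least one oligo.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import canonical_window_codes, word_to_code
from .markov_background import MarkovModel, canonical_word_probability
from .selex_io import KmerTable, SelexRound

logger = logging.getLogger(__name__)


class PipelineAbort(RuntimeError):
    """The method's preconditions fail for this TF (e.g. no canonical
    signal in the selected round)."""


@dataclass
class FilterConfig:
    min_count: int = 100
    fimo_pvalue: float = 1e-4
    min_alone_fraction: float = 0.05
    ror_floor: float = 1.0

    def __post_init__(self):
        for name in ("min_count", "fimo_pvalue", "min_alone_fraction",
                     "ror_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class LmerRecord:
    """One candidate L-mer and everything the pipeline learned about it."""

    word: str                      # canonical form
    count: int
    entropy: float
    enrichment: float = math.nan
    rank: int | None = None
    klass: str = "candidate"       # candidate|motif|nonmotif|discarded
    ror: list[float] = field(default_factory=list)
    alone_oligos: int | None = None
    discard_reason: str = ""

    @property
    def code(self) -> int:
        return word_to_code(self.word)


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping-dinucleotide frequencies
    of a sequence, read in its forward orientation."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    n = len(seq) - 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def entropy_floor(matched_words) -> float:
    """Minimum dinucleotide entropy over the canonical-motif match words."""
    words = list(matched_words)
    if not words:
        raise PipelineAbort(
            "no canonical-motif matches in the selected round: the method "
            "requires canonical signal to calibrate the entropy filter"
        )
    return min(dinucleotide_entropy(w) for w in words)


def initial_lmer_records(
    selected: KmerTable,
    floor: float,
    min_count: int = 100,
) -> tuple[list[LmerRecord], dict]:
    """Build ledger records for canonical L-mers passing the count and
    entropy filters; the audit dict reports how many fell to each."""
    n_total = len(selected.counts)
    records = []
    n_entropy = 0
    for word in selected.words(min_count=min_count):
        h = dinucleotide_entropy(word)
        if h < floor:
            n_entropy += 1
            continue
        records.append(
            LmerRecord(word=word, count=selected.count(word), entropy=h)
        )
    audit = {
        "total_distinct": n_total,
        "below_min_count": n_total - len(selected.words(min_count=min_count)),
        "below_entropy_floor": n_entropy,
        "surviving": len(records),
    }
    return records, audit


def compute_enrichments(
    records: list[LmerRecord], selected: KmerTable, model: MarkovModel
) -> None:
    """Set enrichment = P_R(w)/P0(w) and 1-based descending ranks."""
    for rec in records:
        p_r = selected.frequency(rec.word)
        p_0 = max(canonical_word_probability(model, rec.word), 1e-300)
        rec.enrichment = p_r / p_0
    for rank, rec in enumerate(
        sorted(records, key=lambda r: (-r.enrichment, r.word)), start=1
    ):
        rec.rank = rank


def match_intervals_by_oligo(matches) -> dict[int, list[tuple[int, int]]]:
    """Group scan matches by oligo index (sequence ids are row indices)."""
    out: dict[int, list[tuple[int, int]]] = {}
    for m in matches:
        out.setdefault(int(m.sequence_id), []).append((m.start, m.end))
    return out


def classify_lmers(
    records: list[LmerRecord],
    matches_by_oligo: dict[int, list[tuple[int, int]]],
    selected_round: SelexRound,
    L: int,
) -> None:
    """Split records into motif / nonmotif / discarded.

    A word is a motif L-mer if, in at least one oligo, one of its
    occurrence windows contains or is contained in a canonical-motif match
    interval.  Every word with enrichment strictly below the least
    enriched motif L-mer is discarded (the rank cut; enrichment ties with
    the lowest motif L-mer survive).
    """
    if any(rec.rank is None for rec in records):
        raise ValueError("enrichment ranks must be computed first")
    by_code = {rec.code: rec for rec in records}
    codes, valid = canonical_window_codes(selected_round.matrix, L)
    npos = codes.shape[1]
    motif_codes: set[int] = set()
    for i, intervals in matches_by_oligo.items():
        for s, e in intervals:
            # window [p, p+L) contains the match: p <= s and p+L >= e
            if L >= e - s:
                lo, hi = max(0, e - L), min(s, npos - 1)
            # match contains the window: s <= p and e >= p+L
            else:
                lo, hi = s, min(e - L, npos - 1)
            for p in range(lo, hi + 1):
                if valid[i, p]:
                    motif_codes.add(int(codes[i, p]))
    motif_recs = [rec for rec in records if rec.code in motif_codes]
    if not motif_recs:
        raise PipelineAbort(
            "no motif L-mers: canonical matches do not coincide with any "
            "surviving L-mer"
        )
    min_motif_enrichment = min(rec.enrichment for rec in motif_recs)
    for rec in records:
        if rec.code in motif_codes:
            rec.klass = "motif"
        elif rec.enrichment < min_motif_enrichment:
            rec.klass = "discarded"
            rec.discard_reason = "ranked below lowest motif L-mer"
        else:
            rec.klass = "nonmotif"


def ror_filter(
    word: str, round_tables: list[KmerTable], ror_floor: float = 1.0
) -> tuple[bool, list[float]]:
    """Round-over-round frequency ratios across consecutive rounds.

    Fails if any ratio drops below ``ror_floor``.  A word appearing from
    nothing scores +inf for that pair (appearance is enrichment); a word
    absent from both rounds of a pair fails.
    """
    if len(round_tables) < 2:
        raise ValueError("need at least two rounds for a RoR profile")
    freqs = [t.frequency(word) for t in round_tables]
    ratios: list[float] = []
    ok = True
    for a, b in zip(freqs, freqs[1:]):
        if a == 0 and b == 0:
            ratios.append(math.nan)
            ok = False
        elif a == 0:
            ratios.append(math.inf)
        else:
            r = b / a
            ratios.append(r)
            if r < ror_floor:
                ok = False
    return ok, ratios


def apply_ror_filter(
    records: list[LmerRecord],
    round_tables: list[KmerTable],
    ror_floor: float = 1.0,
) -> None:
    """Apply the RoR filter to every non-motif record in place."""
    for rec in records:
        if rec.klass != "nonmotif":
            continue
        ok, ratios = ror_filter(rec.word, round_tables, ror_floor)
        rec.ror = ratios
        if not ok:
            rec.klass = "discarded"
            rec.discard_reason = "round-over-round enrichment below floor"


def alone_occurrence_census(
    records: list[LmerRecord], selected_round: SelexRound, L: int
) -> None:
    """Count, for each non-motif word, the oligos where it occurs with no
    motif L-mer; words never occurring alone are discarded."""
    codes, valid = canonical_window_codes(selected_round.matrix, L)
    motif_codes = np.array(
        sorted(rec.code for rec in records if rec.klass == "motif"),
        dtype=np.int64,
    )
    flat_ok = np.where(valid, codes, -1)
    has_motif = np.isin(flat_ok, motif_codes).any(axis=1)
    rows_wo = np.flatnonzero(~has_motif)
    alone_counts: dict[int, int] = {}
    if rows_wo.size:
        sub = flat_ok[rows_wo]
        # one hit per (oligo, word): dedupe row/code pairs before counting
        row_idx = np.repeat(rows_wo, sub.shape[1])
        pair = np.stack([sub.ravel(), row_idx], axis=1)
        pair = pair[pair[:, 0] >= 0]
        uniq = np.unique(pair, axis=0)
        codes_u, counts_u = np.unique(uniq[:, 0], return_counts=True)
        alone_counts = dict(zip(codes_u.tolist(), counts_u.tolist()))
    for rec in records:
        if rec.klass != "nonmotif":
            continue
        rec.alone_oligos = alone_counts.get(rec.code, 0)
        if rec.alone_oligos == 0:
            rec.klass = "discarded"
            rec.discard_reason = "always co-occurs with motif L-mers"


def ledger_frame(records: list[LmerRecord]) -> pd.DataFrame:
    """The ledger as a DataFrame, the pipeline's main audit artifact."""
    return pd.DataFrame(
        {
            "word": [r.word for r in records],
            "count": [r.count for r in records],
            "entropy": [r.entropy for r in records],
            "enrichment": [r.enrichment for r in records],
            "rank": [r.rank for r in records],
            "klass": [r.klass for r in records],
            "ror": [",".join(f"{x:.4g}" for x in r.ror) for r in records],
            "alone_oligos": [r.alone_oligos for r in records],
            "discard_reason": [r.discard_reason for r in records],
        }
    )
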