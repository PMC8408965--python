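"""Cluster-head clustering of L-mers into motifs.

A cluster head is an l-mer (l = 8, or L - 2 for short effective lengths)
covering the maximum number of unassigned L-mers within m mismatches
(m = 2, or 1 when l <= 5), counting both orientations.  Covered L-mers
are aligned at their minimum-mismatch anchor, N-padded to a common width,
and turned into a PWM by per-column counting with N contributing 0.25 to
every base.  Tied heads branch into independent clustering runs; the
resulting clusters are pooled and duplicates that arise from branching
are resolved later by the shared-L-mer dedup step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ._seq import encode, reverse_complement
from .motif_model import Pwm
from .selex_io import SelexRound

logger = logging.getLogger(__name__)


def head_params(L: int) -> tuple[int, int]:
    """Head length l and mismatch budget m as functions of L."""
    l = 8 if L >= 8 else L - 2
    if l < 1:
        raise ValueError(f"effective length {L} too short to cluster")
    m = 2 if l > 5 else 1
    return l, m


@dataclass(frozen=True)
class ClusterHead:
    word: str
    l: int
    m: int
    coverage: int = 0


@dataclass
class Member:
    word: str           # canonical L-mer
    offset: int         # head start within the oriented word
    orientation: str    # '+' word as-is, '-' reverse complemented
    mismatches: int

    @property
    def oriented_word(self) -> str:
        return self.word if self.orientation == "+" else reverse_complement(self.word)


@dataclass
class MotifCluster:
    head: ClusterHead
    members: list[Member]
    pwm: Pwm
    kind: str = "noncanonical"   # canonical | noncanonical
    alone_fraction: float | None = None
    dmin: float | None = None
    pvalue: float | None = None
    significant: bool | None = None

    @property
    def member_words(self) -> frozenset[str]:
        return frozenset(m.word for m in self.members)

    @property
    def consensus(self) -> str:
        return self.pwm.consensus


def _mismatches(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def covers(head_word: str, L_word: str, m: int):
    """Best placement of a head within an L-mer, or None.

    Tries the head against the word and against its reverse complement at
    every offset; returns the minimum-mismatch ``(offset, orientation,
    mismatches)`` with offset measured in the oriented word.  Ties resolve
    toward the offset closest to the middle of the word, then leftmost,
    then '+' orientation.  None when the minimum exceeds ``m``.
    """
    l = len(head_word)
    if l > len(L_word):
        return None
    h = encode(head_word)
    best = None
    mid = (len(L_word) - l) / 2
    for orientation, word in (("+", L_word), ("-", reverse_complement(L_word))):
        w = encode(word)
        for off in range(len(L_word) - l + 1):
            mm = _mismatches(h, w[off : off + l])
            key = (mm, abs(off - mid), off, 0 if orientation == "+" else 1)
            if best is None or key < best[0]:
                best = (key, (off, orientation, mm))
    off, orientation, mm = best[1]
    if mm > m:
        return None
    return off, orientation, mm


def find_cluster_heads(words, l: int, m: int) -> list[ClusterHead]:
    """All maximum-coverage cluster heads over a word set.

    Candidate heads are the l-length substrings of the words themselves
    (a head covering many words within m mismatches almost surely occurs
    verbatim in one), taken in canonical form.
    """
    words = list(words)
    if not words:
        raise ValueError("cannot pick a head from an empty word set")
    if any(l > len(w) for w in words):
        raise ValueError("head length exceeds word length")
    candidates: set[str] = set()
    for w in words:
        for off in range(len(w) - l + 1):
            sub = w[off : off + l]
            rc = reverse_complement(sub)
            candidates.add(min(sub, rc))
    best_cov = 0
    cover_map: dict[str, int] = {}
    for cand in candidates:
        cov = sum(1 for w in words if covers(cand, w, m) is not None)
        cover_map[cand] = cov
        best_cov = max(best_cov, cov)
    heads = sorted(c for c, cov in cover_map.items() if cov == best_cov)
    return [ClusterHead(word=h, l=l, m=m, coverage=best_cov) for h in heads]


def build_cluster(head: ClusterHead, unassigned_words, kind: str = "noncanonical") -> MotifCluster:
    """Align the words a head covers and derive the cluster PWM.

    Members found in '-' orientation are reverse complemented before
    alignment; alignment anchors each oriented word so its head occurrence
    starts in the same column, N-pads to a common width, and counts bases
    per column (N adds 0.25 to each base).
    """
    members: list[Member] = []
    for w in unassigned_words:
        hit = covers(head.word, w, head.m)
        if hit is not None:
            off, orientation, mm = hit
            members.append(Member(word=w, offset=off, orientation=orientation,
                                  mismatches=mm))
    if not members:
        raise ValueError("head covers no word in the given set")
    max_left = max(mb.offset for mb in members)
    max_right = max(len(mb.word) - mb.offset for mb in members)
    width = max_left + max_right
    counts = np.zeros((width, 4))
    for mb in members:
        seq = encode(mb.oriented_word)
        start = max_left - mb.offset
        counts[:start] += 0.25
        counts[start : start + len(seq), :] += np.eye(4)[seq]
        counts[start + len(seq) :] += 0.25
    pwm = Pwm(
        name=f"cluster_{head.word}",
        matrix=counts / counts.sum(axis=1, keepdims=True),
        source=f"{kind}_cluster",
    )
    return MotifCluster(head=replace(head, coverage=len(members)),
                        members=members, pwm=pwm, kind=kind)


def cluster_all(
    words,
    L: int,
    max_clusters: int = 5,
    kind: str = "noncanonical",
    branch_budget: int = 8,
) -> list[MotifCluster]:
    """Iteratively peel off clusters until words run out or the cluster cap
    is reached; tied heads branch into independent runs (bounded by
    ``branch_budget``; excess ties resolve lexicographically)."""
    words = sorted(set(words))
    if not words:
        raise ValueError("no words to cluster")
    l, m = head_params(L)
    states: list[tuple[tuple[str, ...], tuple]] = [(tuple(words), ())]
    done: list[tuple] = []
    while states:
        unassigned, clusters = states.pop()
        if not unassigned or len(clusters) >= max_clusters:
            done.append(clusters)
            continue
        heads = find_cluster_heads(unassigned, l, m)
        if len(heads) > 1 and len(states) + len(heads) > branch_budget:
            logger.warning(
                "%d tied heads exceed branch budget %d; keeping the "
                "lexicographically first", len(heads), branch_budget)
            heads = heads[:1]
        for head in heads:
            cluster = build_cluster(head, unassigned, kind=kind)
            remaining = tuple(
                w for w in unassigned if w not in cluster.member_words
            )
            states.append((remaining, clusters + (cluster,)))
    # pool branches; clusters with identical member sets are the same
    # cluster rediscovered under a different (tied) head
    seen: set[frozenset] = set()
    out: list[MotifCluster] = []
    pooled = [c for clusters in done for c in clusters]
    for c in sorted(pooled, key=lambda c: c.head.word):
        if c.member_words not in seen:
            seen.add(c.member_words)
            out.append(c)
    return out


def alone_fraction_filter(
    noncanon_clusters: list[MotifCluster],
    selected_round: SelexRound,
    canonical_clusters: list[MotifCluster],
    min_alone_fraction: float = 0.05,
) -> list[MotifCluster]:
    """Fraction of oligos each non-canonical cluster explains alone.

    A cluster occurs in an oligo if any member L-mer occurs on either
    strand; it occurs alone if no canonical-cluster member occurs.  Oligos
    are attributed greedily to clusters in decreasing member-count order so
    each oligo counts for at most one cluster.  Clusters explaining fewer
    than ``min_alone_fraction`` of the oligos are dropped.
    """
    n = selected_round.n_oligos
    if n == 0:
        raise ValueError("empty selected round")
    canon_hit = np.zeros(n, dtype=bool)
    for c in canonical_clusters:
        canon_hit |= _occurrence_rows(c, selected_round)
    taken = np.zeros(n, dtype=bool)
    kept: list[MotifCluster] = []
    order = sorted(
        noncanon_clusters,
        key=lambda c: (-len(c.members), c.head.word),
    )
    for c in order:
        rows = _occurrence_rows(c, selected_round)
        alone = rows & ~canon_hit & ~taken
        taken |= alone
        c.alone_fraction = float(alone.sum()) / n
        if c.alone_fraction >= min_alone_fraction:
            kept.append(c)
        else:
            logger.info("cluster %s dropped: alone fraction %.4f < %.2f",
                        c.head.word, c.alone_fraction, min_alone_fraction)
    return kept


def _occurrence_rows(cluster: MotifCluster, round: SelexRound) -> np.ndarray:
    """Boolean per-oligo: does any member word occur (either strand)?"""
    from ._seq import canonical_window_codes, word_to_code

    lengths = {len(mb.word) for mb in cluster.members}
    hit = np.zeros(round.n_oligos, dtype=bool)
    for k in lengths:
        codes, valid = canonical_window_codes(round.matrix, k)
        member_codes = np.array(
            sorted({word_to_code(mb.word) for mb in cluster.members
                    if len(mb.word) == k}),
            dtype=np.int64,
        )
        flat_ok = np.where(valid, codes, -1)
        hit |= np.isin(flat_ok, member_codes).any(axis=1)
    return hit
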