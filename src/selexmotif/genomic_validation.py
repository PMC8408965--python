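"""Downstream genomic statistics for discovered motifs.

Discovered (cluster) motifs occur in a sequence when any constituent
L-mer occurs exactly on either strand; canonical motifs may be detected
either the same way (from canonical clusters) or by PWM scanning at the
match p-value used during discovery.  On top of that asymmetric pair of
definitions this module computes: the fraction of ChIP-seq peaks a motif
explains alone, motif enrichment e(m) against shuffled-L-mer /
dinucleotide-shuffled-peak / matched-genomic controls, overlap fractions
with regulatory annotations, promoter Jaccard statistics, conservation
comparisons, and re-discovery in an independent SELEX dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._seq import reverse_complement
from .lmer_clustering import MotifCluster, cluster_all
from .motif_model import Pwm, scan_sequences
from .motif_significance import motif_distance
from .selex_io import SelexRound, count_kmers

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    dataset: str = ""
    sequence: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("peak start must be < end")
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError("peak sequence length must equal end - start")


@dataclass
class EnrichmentReport:
    motif_id: str
    control_kind: str  # shuffled_lmers | dinuc_shuffled_peaks | matched_genomic
    e_m: float
    per_dataset: dict[str, float] = field(default_factory=dict)


@dataclass
class ConservationReport:
    motif_id: str
    per_dataset: dict[str, tuple[float, float, int, int]] = field(default_factory=dict)
    fraction_similar: float = float("nan")


# -- basic occurrence machinery --------------------------------------------


def count_occurrences(word: str, sequence: str) -> int:
    """Overlapping occurrences of a word on either strand of a sequence."""
    total = 0
    for w in {word, reverse_complement(word)}:
        start = 0
        while True:
            i = sequence.find(w, start)
            if i < 0:
                break
            total += 1
            start = i + 1
    return total


def motif_occurs(cluster: MotifCluster, sequence: str):
    """Does any member L-mer occur in the sequence (either strand)?

    Returns ``(bool, intervals)`` with intervals as (start, end, strand,
    word) in sequence coordinates.
    """
    intervals = []
    for word in sorted(cluster.member_words):
        for w, strand in ((word, "+"), (reverse_complement(word), "-")):
            if strand == "-" and w == word:
                continue
            start = 0
            while True:
                i = sequence.find(w, start)
                if i < 0:
                    break
                intervals.append((i, i + len(w), strand, word))
                start = i + 1
    intervals.sort()
    return bool(intervals), intervals


def _canonical_hit_mask(canonical, sequences, fimo_pvalue: float = 1e-4) -> np.ndarray:
    """Per-sequence flag: does any canonical motif occur?

    ``canonical`` is a list of :class:`MotifCluster` (member-word matching)
    and/or :class:`Pwm` (FIMO-style scan at ``fimo_pvalue``).
    """
    seqs = list(sequences)
    hit = np.zeros(len(seqs), dtype=bool)
    pwms = [c for c in canonical if isinstance(c, Pwm)]
    clusters = [c for c in canonical if isinstance(c, MotifCluster)]
    for cl in clusters:
        for i, s in enumerate(seqs):
            if not hit[i] and motif_occurs(cl, s)[0]:
                hit[i] = True
    for pwm in pwms:
        ids = [str(i) for i in range(len(seqs))]
        for m in scan_sequences(pwm, seqs, pvalue=fimo_pvalue, sequence_ids=ids):
            hit[int(m.sequence_id)] = True
    return hit


# -- peak statistics --------------------------------------------------------


def peak_alone_fraction(
    noncanon_cluster: MotifCluster,
    canonical,
    peaks_by_dataset: dict[str, list[Peak]],
    fimo_pvalue: float = 1e-4,
):
    """Mean (over datasets) fraction of peaks where the non-canonical
    motif occurs and no canonical motif does."""
    per_dataset = {}
    for dset, peaks in peaks_by_dataset.items():
        if not peaks:
            logger.warning("dataset %s has no peaks; skipped", dset)
            continue
        seqs = [p.sequence for p in peaks]
        canon_hit = _canonical_hit_mask(canonical, seqs, fimo_pvalue)
        alone = sum(
            1
            for p, ch in zip(peaks, canon_hit)
            if not ch and motif_occurs(noncanon_cluster, p.sequence)[0]
        )
        per_dataset[dset] = alone / len(peaks)
    if not per_dataset:
        raise ValueError("no dataset with peaks")
    return float(np.mean(list(per_dataset.values()))), per_dataset


def shuffle_word(word: str, rng: np.random.Generator) -> str:
    """Seeded uniform letter permutation of a word, re-drawn until it
    differs from the word when any different permutation exists."""
    if len(set(word)) == 1:
        logger.warning("word %s has a unique arrangement; shuffle is itself",
                       word)
        return word
    while True:
        perm = rng.permutation(len(word))
        out = "".join(word[i] for i in perm)
        if out != word:
            return out


def enrichment_shuffled_lmers(
    cluster: MotifCluster,
    peaks_by_dataset: dict[str, list[Peak]],
    seed: int = 0,
) -> EnrichmentReport:
    """e(m) with each member L-mer's letter-shuffled version as control.

    Per member l and dataset d the contribution is
    (n(l, d) + 1) / (n(l', d) + 1); contributions average over members,
    then over datasets.
    """
    rng = np.random.default_rng(seed)
    members = sorted(cluster.member_words)
    if not members:
        raise ValueError("cluster has no members")
    shuffles = {w: shuffle_word(w, rng) for w in members}
    per_dataset = {}
    for dset, peaks in peaks_by_dataset.items():
        seqs = [p.sequence for p in peaks]
        vals = []
        for w in members:
            n_w = sum(count_occurrences(w, s) for s in seqs)
            n_s = sum(count_occurrences(shuffles[w], s) for s in seqs)
            vals.append((n_w + 1) / (n_s + 1))
        per_dataset[dset] = float(np.mean(vals))
    e_m = float(np.mean(list(per_dataset.values())))
    return EnrichmentReport(
        motif_id=cluster.head.word, control_kind="shuffled_lmers",
        e_m=e_m, per_dataset=per_dataset,
    )


def enrichment_vs_controls(
    cluster: MotifCluster,
    peaks_by_dataset: dict[str, list[Peak]],
    controls_by_dataset: dict[str, list[str]],
    control_kind: str = "dinuc_shuffled_peaks",
) -> EnrichmentReport:
    """e(m) with per-dataset control sequence sets (dinucleotide-shuffled
    peaks or user-supplied matched genomic sequences)."""
    members = sorted(cluster.member_words)
    per_dataset = {}
    for dset, peaks in peaks_by_dataset.items():
        if dset not in controls_by_dataset:
            logger.warning("no control for dataset %s; skipped", dset)
            continue
        seqs = [p.sequence for p in peaks]
        ctrl = controls_by_dataset[dset]
        vals = []
        for w in members:
            n_w = sum(count_occurrences(w, s) for s in seqs)
            n_c = sum(count_occurrences(w, s) for s in ctrl)
            vals.append((n_w + 1) / (n_c + 1))
        per_dataset[dset] = float(np.mean(vals))
    if not per_dataset:
        raise ValueError("no dataset has a matching control")
    return EnrichmentReport(
        motif_id=cluster.head.word, control_kind=control_kind,
        e_m=float(np.mean(list(per_dataset.values()))),
        per_dataset=per_dataset,
    )


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Euler-path dinucleotide shuffle: a random sequence with exactly the
    original's dinucleotide count multiset and the same first and last
    letters (Altschul-Erickson style)."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    seq = seq.upper()
    letters = sorted(set(seq))
    edges: dict[str, list[str]] = {a: [] for a in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # choose a random "last edge" per vertex so the chosen edges form a
    # tree pointing at the final vertex, then randomize the rest
    while True:
        last_edge = {}
        for a in letters:
            if a == last or not edges[a]:
                continue
            last_edge[a] = edges[a][rng.integers(len(edges[a]))]
        ok = True
        for a in last_edge:
            seen = {a}
            cur = a
            while cur != last:
                nxt = last_edge.get(cur)
                if nxt is None or nxt in seen:
                    ok = False
                    break
                seen.add(nxt)
                cur = nxt
            if not ok:
                break
        if ok:
            break
    pools: dict[str, list[str]] = {}
    for a in letters:
        pool = list(edges[a])
        if a in last_edge:
            pool.remove(last_edge[a])
        rng.shuffle(pool)
        if a in last_edge:
            pool.append(last_edge[a])
        pools[a] = pool
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_dinuc_shuffled_controls(
    peaks_by_dataset: dict[str, list[Peak]], seed: int = 0
) -> dict[str, list[str]]:
    rng = np.random.default_rng(seed)
    return {
        dset: [dinucleotide_shuffle(p.sequence, rng) for p in peaks]
        for dset, peaks in peaks_by_dataset.items()
    }


# -- annotation overlap -----------------------------------------------------


def read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return list(df.itertuples(index=False, name=None))


def regulatory_fraction(occurrence_intervals, regions) -> float:
    """Fraction of genome-coordinate occurrences overlapping (>= 1 bp) any
    region; intervals and regions are (chrom, start, end) triples."""
    occurrence_intervals = list(occurrence_intervals)
    if not occurrence_intervals:
        return 0.0
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    n_hit = sum(
        1
        for chrom, start, end in occurrence_intervals
        if chrom in trees and trees[chrom].overlap(start, end)
    )
    return n_hit / len(occurrence_intervals)


def promoter_jaccard(noncanon_promoters, canon_promoters) -> float:
    """Jaccard index between the promoter sets hit by the two motif types;
    0 when both sets are empty (logged)."""
    a, b = set(noncanon_promoters), set(canon_promoters)
    union = a | b
    if not union:
        logger.info("both promoter sets empty; Jaccard defined as 0")
        return 0.0
    return len(a & b) / len(union)


def promoter_comparison(
    noncanon_intervals, canon_intervals, promoters,
    min_promoter_fraction: float = 0.10,
):
    """Promoter Jaccard with the eligibility gate: computed only when at
    least ``min_promoter_fraction`` of both motif types' occurrences fall
    in promoters.  Returns ``(jaccard or None, frac_noncanon, frac_canon)``.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, (chrom, start, end) in enumerate(promoters):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, idx)

    def hit_promoters(intervals):
        hits = set()
        n_in = 0
        intervals = list(intervals)
        for chrom, start, end in intervals:
            found = trees[chrom].overlap(start, end) if chrom in trees else ()
            if found:
                n_in += 1
                hits.update(iv.data for iv in found)
        frac = n_in / len(intervals) if intervals else 0.0
        return hits, frac

    nc_hits, nc_frac = hit_promoters(noncanon_intervals)
    c_hits, c_frac = hit_promoters(canon_intervals)
    if nc_frac < min_promoter_fraction or c_frac < min_promoter_fraction:
        return None, nc_frac, c_frac
    return promoter_jaccard(nc_hits, c_hits), nc_frac, c_frac


# -- conservation -----------------------------------------------------------


def read_score_track(path) -> dict[str, dict[int, float]]:
    """Per-base conservation scores as TSV (chrom, 0-based pos, score)."""
    track: dict[str, dict[int, float]] = {}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "score"], comment="#")
    for chrom, grp in df.groupby("chrom"):
        track[str(chrom)] = dict(zip(grp["pos"].astype(int), grp["score"]))
    return track


def occurrence_mean_score(chrom: str, start: int, end: int,
                          track: dict[str, dict[int, float]]) -> float | None:
    scores = track.get(chrom, {})
    vals = [scores[p] for p in range(start, end) if p in scores]
    if not vals:
        return None
    return float(np.mean(vals))


def conservation_compare(noncanon_mean_scores, canon_mean_scores):
    """Two-sample Kolmogorov-Smirnov test between per-occurrence mean
    conservation scores (asymptotic p-value)."""
    a = np.asarray(list(noncanon_mean_scores), dtype=float)
    b = np.asarray(list(canon_mean_scores), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be nonempty")
    if min(a.size, b.size) < 10:
        logger.warning("KS comparison with n < 10; asymptotic p unreliable")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# -- independent-dataset validation -----------------------------------------


def validate_independent(
    noncanon_cluster: MotifCluster,
    initial_round: SelexRound,
    designated_round: SelexRound,
    max_clusters: int = 5,
):
    """Re-discover a non-canonical motif in an independent SELEX dataset.

    Member L-mers' enrichments (designated-round frequency over
    initial-round frequency) are computed, members below 1 dropped, the
    survivors re-clustered, and each resulting PWM's distance to the
    original motif reported.  Returns ``(best_pwm, distance)`` or ``None``.
    """
    members = sorted(noncanon_cluster.member_words)
    lengths = {len(w) for w in members}
    survivors = []
    for k in lengths:
        t_init = count_kmers(initial_round, k)
        t_sel = count_kmers(designated_round, k)
        for w in members:
            if len(w) != k:
                continue
            f0, f1 = t_init.frequency(w), t_sel.frequency(w)
            if f0 == 0 and f1 == 0:
                continue
            enr = np.inf if f0 == 0 else f1 / f0
            if enr >= 1:
                survivors.append(w)
    if not survivors:
        return None
    L = max(len(w) for w in survivors)
    clusters = cluster_all(survivors, L, max_clusters=max_clusters)
    best = None
    for c in clusters:
        d = motif_distance(c.pwm, noncanon_cluster.pwm)
        if d is None:
            continue
        if best is None or d < best[1]:
            best = (c.pwm, d)
    return best
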