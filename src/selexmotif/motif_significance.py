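"""Statistical significance of discovered motifs against the canonical set.

The distance D between two motifs is the minimum, over all l-column
windows of both trimmed motifs and both orientations of one of them, of
the Euclidean distance between the flattened probability blocks divided
by the window length (l = 8, shrunk to the smaller trimmed width).  Each
discovered motif's D_min to the canonical (CIS-BP) collection is compared
with a normal model fitted to the canonical clusters' own D_min values;
one-tailed p-values are corrected per TF by Benjamini-Hochberg at 5% FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmer_clustering import MotifCluster
from .motif_model import Pwm, trim_motif

logger = logging.getLogger(__name__)


@dataclass
class SimilarityResult:
    cluster_id: str
    dmin: float
    pvalue: float | None = None
    significant: bool | None = None


def motif_distance(a: Pwm, b: Pwm, l: int = 8,
                   ic_threshold: float = 0.25) -> float | None:
    """Normalized minimum sub-motif Euclidean distance between two motifs.

    Both motifs are first trimmed of flanking columns with information
    content below ``ic_threshold`` bits; the window length is min(l,
    smaller trimmed width).  Returns None when either motif trims to
    nothing.
    """
    ta, tb = trim_motif(a, ic_threshold), trim_motif(b, ic_threshold)
    if ta is None or tb is None:
        logger.warning("motif distance undefined: a motif trims to zero width")
        return None
    lw = min(l, ta.width, tb.width)
    best = np.inf
    for bmat in (tb.matrix, tb.reverse_complement().matrix):
        for i in range(ta.width - lw + 1):
            wa = ta.matrix[i : i + lw]
            for j in range(tb.width - lw + 1):
                wb = bmat[j : j + lw]
                d = float(np.linalg.norm(wa - wb)) / lw
                best = min(best, d)
    return best


def dmin(cluster_pwm: Pwm, cisbp_set, l: int = 8) -> float | None:
    """Minimum motif distance from a PWM to the canonical collection."""
    cisbp_set = list(cisbp_set)
    if not cisbp_set:
        raise ValueError("canonical motif set is empty")
    dists = [motif_distance(cluster_pwm, c, l=l) for c in cisbp_set]
    dists = [d for d in dists if d is not None]
    if not dists:
        return None
    return min(dists)


def noncanonical_pvalues(noncanon_dmins, canon_dmins) -> list[float]:
    """Upper-tail normal p-values of non-canonical D_min values under the
    canonical D_min distribution (sample mean, n-1 standard deviation)."""
    canon = np.asarray(list(canon_dmins), dtype=float)
    if canon.size < 2:
        raise ValueError("need >= 2 canonical D_min values to calibrate")
    mu = float(canon.mean())
    sigma = float(canon.std(ddof=1))
    if sigma == 0:
        raise ValueError("canonical D_min values have zero variance")
    return [
        float(stats.norm.sf((d - mu) / sigma)) for d in noncanon_dmins
    ]


def bh_select(pvalues, q: float = 0.05) -> list[bool]:
    """Benjamini-Hochberg step-up at level q over one family."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


def score_noncanonical_clusters(
    noncanon_clusters: list[MotifCluster],
    canon_clusters: list[MotifCluster],
    cisbp_set: list[Pwm],
    q: float = 0.05,
    l: int = 8,
) -> list[MotifCluster]:
    """Annotate clusters with D_min, p-value and BH significance; return
    the significant ones after shared-L-mer dedup."""
    canon_dmins = []
    for c in canon_clusters:
        d = dmin(c.pwm, cisbp_set, l=l)
        c.dmin = d
        if d is not None:
            canon_dmins.append(d)
    evaluable = []
    for c in noncanon_clusters:
        c.dmin = dmin(c.pwm, cisbp_set, l=l)
        if c.dmin is None:
            logger.warning("cluster %s excluded: D_min undefined", c.head.word)
        else:
            evaluable.append(c)
    if len(canon_dmins) < 2 or np.std(canon_dmins, ddof=1) == 0:
        logger.warning(
            "TF unevaluable: fewer than 2 canonical D_min values or zero "
            "variance; no significance calls"
        )
        for c in evaluable:
            c.significant = None
        return []
    pvals = noncanonical_pvalues([c.dmin for c in evaluable], canon_dmins)
    flags = bh_select(pvals, q=q)
    for c, p, sig in zip(evaluable, pvals, flags):
        c.pvalue = p
        c.significant = sig
    significant = [c for c in evaluable if c.significant]
    return dedup_shared_lmers(significant)


def dedup_shared_lmers(clusters: list[MotifCluster]) -> list[MotifCluster]:
    """Resolve branch duplicates: while two clusters share a member L-mer,
    drop the one less different from the canonical motifs (smaller D_min;
    ties drop the smaller membership, then the lexicographically later
    head)."""
    alive = list(clusters)
    while True:
        dropped = None
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                a, b = alive[i], alive[j]
                if a.member_words & b.member_words:
                    ka = (a.dmin if a.dmin is not None else -np.inf,
                          len(a.members), [-ord(ch) for ch in a.head.word])
                    kb = (b.dmin if b.dmin is not None else -np.inf,
                          len(b.members), [-ord(ch) for ch in b.head.word])
                    dropped = a if ka < kb else b
                    break
            if dropped:
                break
        if dropped is None:
            return alive
        alive.remove(dropped)
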