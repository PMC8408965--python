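"""Effective binding-site length selection.

For each candidate word length k, the divergence between the selected
round's k-mer distribution and the round #0 background is measured by a
KL divergence over the partition {each word counted >= min_count} plus a
single combined group holding all remaining words.  The effective length L
is the k maximizing this divergence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .markov_background import MarkovModel, canonical_word_probability
from .selex_io import KmerTable, SelexRound, count_kmers

logger = logging.getLogger(__name__)

P0_FLOOR = 1e-300


@dataclass
class KlProfile:
    """Per-k divergence records and the chosen effective length."""

    records: list[tuple[int, float, int]] = field(default_factory=list)
    chosen_L: int | None = None
    low_signal: bool = False

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tD_KL\tn_S100\n")
            for k, d, n in self.records:
                fh.write(f"{k}\t{d:.8g}\t{n}\n")


def kl_divergence_at_k(
    selected: KmerTable, model: MarkovModel, min_count: int = 100
) -> tuple[float, list[str]]:
    """KL divergence between selected-round and background k-mer
    distributions over the well-counted words.

    S100 = canonical words counted at least ``min_count`` times in the
    selected round; all other words form one combined group whose
    divergence term is added exactly once.  Natural log.
    """
    s100 = selected.words(min_count=min_count)
    if not s100:
        logger.warning("no k-mer at k=%d reaches count %d; D_KL = 0",
                       selected.k, min_count)
        return 0.0, []
    d = 0.0
    p_r_sum = 0.0
    p_0_sum = 0.0
    for w in s100:
        p_r = selected.frequency(w)
        p_0 = max(canonical_word_probability(model, w), P0_FLOOR)
        d += p_r * math.log(p_r / p_0)
        p_r_sum += p_r
        p_0_sum += p_0
    q_r = 1.0 - p_r_sum
    q_0 = 1.0 - p_0_sum
    if q_0 <= 0:
        logger.warning("combined-group background mass <= 0 at k=%d; "
                       "Q term skipped", selected.k)
    elif q_r > 0:
        d += q_r * math.log(q_r / q_0)
    return d, s100


def effective_length(
    selected_round: SelexRound,
    model: MarkovModel,
    k_max: int = 15,
    min_count: int = 100,
    low_signal_floor: float = 1e-3,
) -> KlProfile:
    """Profile D_KL over k in [model.order + 1, k_max] and pick the argmax.

    Ties break toward smaller k (logged).  If the maximum divergence is
    below ``low_signal_floor`` the profile is flagged low-signal.
    """
    k_min = model.order + 1
    k_max = min(k_max, selected_round.oligo_length)
    profile = KlProfile()
    best_d = -np.inf
    best_k = None
    for k in range(max(k_min, 1), k_max + 1):
        table = count_kmers(selected_round, k)
        d, s100 = kl_divergence_at_k(table, model, min_count=min_count)
        profile.records.append((k, d, len(s100)))
        if d > best_d:
            best_d, best_k = d, k
        elif d == best_d:
            logger.info("D_KL tie at k=%d; keeping smaller k=%d", k, best_k)
    profile.chosen_L = best_k
    if best_d < low_signal_floor:
        profile.low_signal = True
        logger.warning("max D_KL %.3g below %.3g: little selection signal",
                       best_d, low_signal_floor)
    return profile
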