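"""Order-r Markov background models of the round #0 library.

The background model supplies word probabilities P0(w) for words too long
to be counted reliably in round #0.  Model order is selected by splitting
the shuffled library in half, fitting orders 0..M on one half and scoring
the coefficient of determination (R^2) between predicted and observed
canonical M-mer frequencies on the other; M is one less than the largest k
at which every observed k-mer still has at least ``min_count`` occurrences.
Counting is double-stranded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import canonical, encode, reverse_complement, window_codes
from .selex_io import SelexRound, count_kmers

logger = logging.getLogger(__name__)


@dataclass
class MarkovModel:
    """Order-r nucleotide chain: initial r-mer distribution + conditionals."""

    order: int
    initial: np.ndarray        # shape (4**order,)
    conditionals: np.ndarray   # shape (4**order, 4)
    trained_on: str = ""

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if not np.allclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.conditionals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every conditional must sum to 1")

    # -- probabilities ----------------------------------------------------

    def raw_probability(self, word: str) -> float:
        """Strand-specific P(word) = P(prefix) * prod P(base | context)."""
        r = self.order
        if len(word) < r:
            raise ValueError(f"word shorter than model order {r}")
        codes = encode(word)
        if (codes == 4).any():
            raise ValueError("cannot evaluate a word containing N")
        ctx = 0
        for b in codes[:r]:
            ctx = ctx * 4 + int(b)
        p = float(self.initial[ctx])
        mask = 4**r
        for b in codes[r:]:
            p *= float(self.conditionals[ctx, int(b)])
            ctx = (ctx * 4 + int(b)) % mask if r > 0 else 0
        return p


def word_probability(model: MarkovModel, word: str) -> float:
    """Strand-symmetrized word probability.

    Returns (P(w) + P(rc(w))) / 2 for non-palindromic words, P(w) for a
    word equal to its own reverse complement.
    """
    rc = reverse_complement(word)
    if rc == word:
        return model.raw_probability(word)
    return 0.5 * (model.raw_probability(word) + model.raw_probability(rc))


def canonical_word_probability(model: MarkovModel, word: str) -> float:
    """Probability that a random window spells w on either strand.

    Comparable with canonical k-mer frequencies from
    :func:`selexmotif.selex_io.count_kmers`: P(w) + P(rc(w)) for
    non-palindromes, P(w) for palindromes.
    """
    rc = reverse_complement(word)
    if rc == word:
        return model.raw_probability(word)
    return model.raw_probability(word) + model.raw_probability(rc)


def fit_markov(sequences, order: int, pseudocount: float = 1.0,
               trained_on: str = "") -> MarkovModel:
    """Fit an order-r model by additive-smoothed double-strand counting."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("cannot fit a model on an empty sequence set")
    if order + 1 > min(len(s) for s in seqs):
        raise ValueError("order + 1 exceeds sequence length")
    n_ctx = 4**order
    trans = np.full((n_ctx, 4), pseudocount, dtype=float)
    init = np.full(n_ctx, pseudocount, dtype=float)

    from ._seq import encode_matrix

    both = seqs + [reverse_complement(s) for s in seqs]
    lengths = {len(s) for s in both}
    for ln in lengths:
        mat = encode_matrix([s for s in both if len(s) == ln])
        codes, valid = window_codes(mat, order + 1)
        flat = codes[valid]
        counts = np.bincount(flat, minlength=4 ** (order + 1)).astype(float)
        trans += counts.reshape(n_ctx, 4)
        if order > 0:
            ccodes, cvalid = window_codes(mat, order)
            init += np.bincount(ccodes[cvalid], minlength=n_ctx).astype(float)
    if order == 0:
        init = np.array([1.0])
    return MarkovModel(
        order=order,
        initial=init / init.sum(),
        conditionals=trans / trans.sum(axis=1, keepdims=True),
        trained_on=trained_on,
    )


@dataclass
class OrderSelectionReport:
    M: int
    optimal_order: int
    r2_by_order: dict[int, float]
    seed: int


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(((observed - predicted) ** 2).sum())
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _predicted_canonical_freqs(model: MarkovModel, words) -> np.ndarray:
    return np.array([canonical_word_probability(model, w) for w in words])


def select_order(round0: SelexRound, min_count: int = 100, seed: int = 0,
                 max_m: int = 8):
    """Select the Markov order for the round #0 background model.

    Returns ``(report, model)`` where the model is refit on the full
    library at the selected order.  ``max_m`` caps the order bound M.
    """
    if round0.n_oligos == 0:
        raise ValueError("round 0 library is empty")
    # M = (largest k with every observed canonical k-mer count >= min_count) - 1
    k = 0
    while k + 1 <= min(round0.oligo_length, max_m + 1):
        table = count_kmers(round0, k + 1)
        if table.counts and min(table.counts.values()) >= min_count:
            k += 1
        else:
            break
    M = k - 1
    if M < 0:
        logger.warning("library too small to bound the order; using order 0")
        M = 0

    rng = np.random.default_rng(seed)
    order_idx = rng.permutation(round0.n_oligos)
    half = round0.n_oligos // 2
    train = [round0.oligos[i] for i in order_idx[:half]]
    valid = [round0.oligos[i] for i in order_idx[half:]]
    eval_k = max(M, 1)
    vtable = count_kmers(
        SelexRound(0, valid, round0.oligo_length), eval_k
    )
    words = vtable.words()
    observed = np.array([vtable.frequency(w) for w in words])

    r2_by_order: dict[int, float] = {}
    for order in range(M + 1):
        model = fit_markov(train, order, trained_on=f"round0-train-seed{seed}")
        r2_by_order[order] = _r2(
            observed, _predicted_canonical_freqs(model, words)
        )
    optimal = max(r2_by_order, key=lambda o: (r2_by_order[o], -o))
    report = OrderSelectionReport(
        M=M, optimal_order=optimal, r2_by_order=r2_by_order, seed=seed
    )
    final = fit_markov(round0.oligos, optimal, trained_on="round0-full")
    return report, final


# -- serialization ----------------------------------------------------------


def write_model(model: MarkovModel, path, seed: int | None = None) -> None:
    """Serialize to TSV: header with order, then context rows (context, A,
    C, G, T) for conditionals and an INITIAL block."""
    from ._seq import code_to_word

    with open(path, "w") as fh:
        fh.write(f"#order={model.order}")
        if seed is not None:
            fh.write(f"\tseed={seed}")
        fh.write("\n#context\tA\tC\tG\tT\n")
        for ctx in range(4**model.order):
            name = code_to_word(ctx, model.order) if model.order else "-"
            row = "\t".join(f"{p:.8g}" for p in model.conditionals[ctx])
            fh.write(f"{name}\t{row}\n")
        fh.write("#initial\n")
        for ctx in range(4**model.order):
            name = code_to_word(ctx, model.order) if model.order else "-"
            fh.write(f"{name}\t{model.initial[ctx]:.8g}\n")


def read_model(path) -> MarkovModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    order = int(lines[0].split("=")[1].split("\t")[0])
    n_ctx = 4**order
    cond = np.zeros((n_ctx, 4))
    init = np.zeros(n_ctx)
    section = "cond"
    i_cond = i_init = 0
    for line in lines[1:]:
        if line.startswith("#initial"):
            section = "init"
            continue
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        if section == "cond":
            cond[i_cond] = [float(x) for x in parts[1:5]]
            i_cond += 1
        else:
            init[i_init] = float(parts[1])
            i_init += 1
    return MarkovModel(order=order, initial=init, conditionals=cond)
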