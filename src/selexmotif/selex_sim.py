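"""HT-SELEX and genomic fixture simulation.

The round-0 library is an i.i.d. draw from a configurable background
(mononucleotide or Markov).  Each selection round resamples oligos with
replacement under an exponential-of-affinity-proxy weighting over a
mixture of binding components (e.g. one canonical PWM and one
non-canonical PWM): each draw
first picks a component by its mixture weight, then an oligo with
probability proportional to exp(stringency * max(0, best score)) under
that component, so the mixture weights are the stationary per-round
composition of binding events.  Which component drove each draw is
recorded as a provenance label in a sidecar manifest — never in the
sequence itself — so downstream recovery can be checked against a ground
truth the pipeline cannot see.

The genomic fixture builder produces a synthetic chromosome with
non-overlapping peaks carrying planted canonical / non-canonical sites in
configured proportions, plus matching regulatory, promoter and
conservation-score annotations and a manifest of expected statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, decode, reverse_complement
from .genomic_validation import Peak
from .markov_background import MarkovModel
from .motif_model import Pwm, log_odds_matrix
from .selex_io import SelexRound


@dataclass
class SimConfig:
    """Study conditions for one simulated HT-SELEX experiment."""

    binding_components: list[tuple[Pwm, float]]
    n_oligos: int = 50_000
    oligo_length: int = 40
    background: object = None        # 4-vector, MarkovModel, or None=uniform
    selection_stringency: float = 0.5  # per bit of best log-odds score
    n_rounds: int = 3
    seed: int = 0

    def __post_init__(self):
        weights = [w for _, w in self.binding_components]
        if any(w <= 0 for w in weights):
            raise ValueError("mixture weights must be positive")
        if weights and not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class SimResult:
    rounds: list[SelexRound]
    provenance: list[np.ndarray]   # per selection round: component index per oligo
    manifest: dict = field(default_factory=dict)

    @property
    def selected(self) -> SelexRound:
        return self.rounds[-1]

    def provenance_share(self, round_index: int | None = None) -> dict[int, float]:
        labels = self.provenance[(round_index or len(self.provenance)) - 1]
        n = labels.size
        return {int(c): float((labels == c).sum()) / n
                for c in np.unique(labels)}

    def alone_oracle_share(self, component: int,
                           components: list[tuple[Pwm, float]]) -> float:
        """Ground-truth share of selected-round oligos attributable to one
        component alone: provenance label equals ``component``, the
        component's consensus occurs (either strand), and no other
        component's consensus does."""
        labels = self.provenance[-1]
        cons = [pwm.consensus for pwm, _ in components]
        rc = [reverse_complement(c) for c in cons]
        n_alone = 0
        for i, oligo in enumerate(self.selected.oligos):
            if labels[i] != component:
                continue
            has = [c in oligo or r in oligo for c, r in zip(cons, rc)]
            if has[component] and not any(
                h for j, h in enumerate(has) if j != component
            ):
                n_alone += 1
        return n_alone / self.selected.n_oligos


def simulate_round0(config: SimConfig, rng: np.random.Generator | None = None) -> SelexRound:
    """Draw the unselected library from the background model."""
    rng = rng or np.random.default_rng(config.seed)
    n, length = config.n_oligos, config.oligo_length
    bg = config.background
    if bg is None:
        bg = np.full(4, 0.25)
    if isinstance(bg, MarkovModel):
        mat = _sample_markov(bg, n, length, rng)
    else:
        bg = np.asarray(bg, dtype=float)
        bg = bg / bg.sum()
        mat = rng.choice(4, size=(n, length), p=bg).astype(np.int8)
    oligos = [decode(row) for row in mat]
    return SelexRound(round_index=0, oligos=oligos, oligo_length=length)


def _sample_markov(model: MarkovModel, n: int, length: int,
                   rng: np.random.Generator) -> np.ndarray:
    r = model.order
    mat = np.zeros((n, length), dtype=np.int8)
    if r == 0:
        p = model.conditionals[0]
        return rng.choice(4, size=(n, length), p=p).astype(np.int8)
    # draw the initial r-mer, then extend column by column
    ctx = rng.choice(4**r, size=n, p=model.initial)
    for j in range(min(r, length)):
        shift = 4 ** (r - 1 - j)
        mat[:, j] = (ctx // shift) % 4
    mask = 4**r
    cum = np.cumsum(model.conditionals, axis=1)
    for j in range(r, length):
        u = rng.random(n)
        base = (u[:, None] > cum[ctx]).sum(axis=1)
        mat[:, j] = base
        ctx = (ctx * 4 + base) % mask
    return mat


def best_scores(round: SelexRound, pwm: Pwm) -> np.ndarray:
    """Best log-odds window score (bits, either strand) per oligo, against
    a uniform background."""
    lo = log_odds_matrix(pwm)
    rev = lo[::-1, ::-1]
    mat = round.matrix
    n, length = mat.shape
    w = pwm.width
    npos = length - w + 1
    if npos < 1:
        return np.full(n, -np.inf)
    sf = np.zeros((n, npos))
    sr = np.zeros((n, npos))
    for t in range(w):
        col = mat[:, t : t + npos]
        safe = np.where(col == 4, 0, col)
        sf += lo[t][safe]
        sr += rev[t][safe]
    return np.maximum(sf.max(axis=1), sr.max(axis=1))


def simulate_selection(
    round: SelexRound, config: SimConfig, rng: np.random.Generator
) -> tuple[SelexRound, np.ndarray]:
    """One selection round: resample to n_oligos from the mixture of
    per-component exponential-score selection distributions; returns the
    new round and the per-oligo provenance label (index of the component
    that drove the draw)."""
    if round.n_oligos == 0:
        raise ValueError("cannot select from an empty round")
    comps = config.binding_components
    s = config.selection_stringency
    weights = np.empty((len(comps), round.n_oligos))
    for c, (pwm, _) in enumerate(comps):
        sc = np.maximum(best_scores(round, pwm), 0.0)
        weights[c] = np.exp(np.minimum(s * sc, 700.0))
    z = weights.sum(axis=1)
    comp_p = np.array([w for _, w in comps], dtype=float)
    comp_p = comp_p / comp_p.sum()
    labels = rng.choice(len(comps), size=config.n_oligos, p=comp_p)
    picks = np.empty(config.n_oligos, dtype=np.int64)
    for c in range(len(comps)):
        idx = np.flatnonzero(labels == c)
        if idx.size:
            p = weights[c] / z[c]
            picks[idx] = rng.choice(round.n_oligos, size=idx.size, p=p)
    oligos = [round.oligos[i] for i in picks]
    new = SelexRound(round_index=round.round_index + 1, oligos=oligos,
                     oligo_length=round.oligo_length)
    return new, labels


def simulate_experiment(config: SimConfig) -> SimResult:
    """Round 0 plus ``n_rounds`` successive selection rounds."""
    rng = np.random.default_rng(config.seed)
    rounds = [simulate_round0(config, rng)]
    provenance = []
    for _ in range(config.n_rounds):
        nxt, labels = simulate_selection(rounds[-1], config, rng)
        rounds.append(nxt)
        provenance.append(labels)
    manifest = {
        "seed": config.seed,
        "n_oligos": config.n_oligos,
        "oligo_length": config.oligo_length,
        "n_rounds": config.n_rounds,
        "selection_stringency": config.selection_stringency,
        "components": [
            {"name": pwm.name, "weight": w, "consensus": pwm.consensus}
            for pwm, w in config.binding_components
        ],
    }
    return SimResult(rounds=rounds, provenance=provenance, manifest=manifest)


# -- standard study conditions ---------------------------------------------


def planted_pwm(consensus: str, certainty: float = 0.9,
                probs=None, name: str | None = None) -> Pwm:
    """A planted motif with one dominant base per position.

    ``certainty`` is the probability of the consensus base (remaining mass
    uniform over the other three); ``probs`` overrides it per position,
    e.g. to give a motif soft shoulders.
    """
    if probs is None:
        probs = [certainty] * len(consensus)
    mat = np.empty((len(consensus), 4))
    for i, (ch, p) in enumerate(zip(consensus, probs)):
        mat[i] = (1 - p) / 3
        mat[i, BASES.index(ch)] = p
    return Pwm(name=name or consensus, matrix=mat, source="planted")


#: canonical motifs for the standard discovery studies: widths of 12 with
#: soft shoulders, giving binding sites a realistic affinity range so the
#: liberal match threshold also picks up weakly selected occurrences.
_SHOULDERS = [0.65, 0.8] + [0.9] * 8 + [0.8, 0.65]


def canonical_study_pwms() -> list[Pwm]:
    return [
        planted_pwm("TAACGTCAGTAT", probs=_SHOULDERS, name="canonical_A"),
        planted_pwm("CTGAGCCTGGAC", probs=_SHOULDERS, name="canonical_B"),
    ]


def noncanonical_study_pwm() -> Pwm:
    # core at Hamming distance >= 4 from both canonical cores in every
    # alignment and orientation
    return planted_pwm("TTGGCCAA", certainty=0.9, name="noncanonical")


def discovery_study(seed: int, n_oligos: int = 20_000) -> SimConfig:
    """Two-binding-mode experiment: 80% canonical (split over two CIS-BP
    style motifs), 20% non-canonical, strong selection over 3 rounds."""
    a1, a2 = canonical_study_pwms()
    return SimConfig(
        binding_components=[(a1, 0.5), (a2, 0.3),
                            (noncanonical_study_pwm(), 0.2)],
        n_oligos=n_oligos, n_rounds=3, selection_stringency=0.5, seed=seed,
    )


def null_study(seed: int, n_oligos: int = 20_000) -> SimConfig:
    """Canonical-binding-only experiment (false-positive control)."""
    a1, a2 = canonical_study_pwms()
    return SimConfig(
        binding_components=[(a1, 0.625), (a2, 0.375)],
        n_oligos=n_oligos, n_rounds=3, selection_stringency=0.5, seed=seed,
    )


def length_recovery_study(seed: int, n_oligos: int = 50_000) -> SimConfig:
    """Single planted width-8 motif for effective-length recovery.

    Selection is calibrated so three rounds enrich site-bearing reads to a
    few percent of the library — the depth-to-enrichment regime in which
    the 100-count divergence statistic resolves site length.
    """
    pwm = planted_pwm("ACGTCAGT", certainty=0.75, name="planted8")
    return SimConfig(
        binding_components=[(pwm, 1.0)], n_oligos=n_oligos, n_rounds=3,
        selection_stringency=0.15, seed=seed,
    )


# -- genomic fixtures -------------------------------------------------------


@dataclass
class GenomeFixture:
    chrom: str
    genome: dict[str, str]
    peaks: list[Peak]
    regulatory: list[tuple[str, int, int]]
    promoters: list[tuple[str, int, int]]
    score_track: dict[str, dict[int, float]]
    manifest: dict

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        for name, rows in (
            ("peaks.bed", [(p.chrom, p.start, p.end) for p in self.peaks]),
            ("regulatory.bed", self.regulatory),
            ("promoters.bed", self.promoters),
        ):
            with open(os.path.join(outdir, name), "w") as fh:
                for chrom, s, e in rows:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        with open(os.path.join(outdir, "scores.tsv"), "w") as fh:
            for chrom, scores in self.score_track.items():
                for pos in sorted(scores):
                    fh.write(f"{chrom}\t{pos}\t{scores[pos]}\n")
        import yaml

        with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(self.manifest, fh)


def _scrub(seq: list[str], forbidden: list[str], rng: np.random.Generator) -> None:
    """Mutate the background until no forbidden word occurs on either
    strand (keeps planted-site counts exact in deterministic fixtures)."""
    words = set(forbidden) | {reverse_complement(w) for w in forbidden}
    text = "".join(seq)
    changed = True
    while changed:
        changed = False
        for w in words:
            i = text.find(w)
            while i >= 0:
                j = i + len(w) // 2
                old = text[j]
                new = BASES[(BASES.index(old) + 1 + rng.integers(3)) % 4]
                text = text[:j] + new + text[j + 1 :]
                changed = True
                i = text.find(w)
    seq[:] = list(text)


def simulate_genome_with_peaks(
    noncanon_word: str,
    canonical_word: str,
    n_peaks: int = 100,
    peak_length: int = 120,
    frac_noncanon_only: float = 0.30,
    frac_canon_only: float = 0.50,
    frac_both: float = 0.0,
    regulatory_frac_of_noncanon_sites: float = 0.5,
    conserved_frac_of_noncanon_sites: float = 0.5,
    promoter_fraction_of_peaks: float = 0.0,
    seed: int = 0,
    gap: int = 30,
) -> GenomeFixture:
    """Deterministic-placement genomic fixture.

    Peaks are laid end to end with ``gap`` spacers on one synthetic
    chromosome.  The first ``round(frac_noncanon_only * n)`` peaks carry
    only the non-canonical word (planted at the peak centre), the next
    block only the canonical word, then peaks with both, and the rest are
    empty.  Background sequence is scrubbed of chance occurrences of
    either word, so occurrence statistics equal the manifest exactly.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrSim"
    n_nc = round(frac_noncanon_only * n_peaks)
    n_c = round(frac_canon_only * n_peaks)
    n_b = round(frac_both * n_peaks)
    if n_nc + n_c + n_b > n_peaks:
        raise ValueError("placement fractions exceed 1")
    categories = (["noncanon"] * n_nc + ["canon"] * n_c + ["both"] * n_b
                  + ["empty"] * (n_peaks - n_nc - n_c - n_b))

    peaks: list[Peak] = []
    noncanon_sites: list[tuple[str, int, int]] = []
    chrom_seq: list[str] = []
    pos = 0
    for pi, cat in enumerate(categories):
        chrom_seq.extend(BASES[b] for b in rng.integers(4, size=gap))
        pos += gap
        peak_seq = [BASES[b] for b in rng.integers(4, size=peak_length)]
        _scrub(peak_seq, [noncanon_word, canonical_word], rng)
        centre = peak_length // 2
        if cat in ("noncanon", "both"):
            off = centre - len(noncanon_word)
            peak_seq[off : off + len(noncanon_word)] = list(noncanon_word)
            noncanon_sites.append((chrom, pos + off, pos + off + len(noncanon_word)))
        if cat in ("canon", "both"):
            off = centre + 2
            peak_seq[off : off + len(canonical_word)] = list(canonical_word)
        peaks.append(Peak(chrom=chrom, start=pos, end=pos + peak_length,
                          dataset="sim", sequence="".join(peak_seq)))
        chrom_seq.extend(peak_seq)
        pos += peak_length
    chrom_seq.extend(BASES[b] for b in rng.integers(4, size=gap))
    genome = {chrom: "".join(chrom_seq)}

    n_reg = round(regulatory_frac_of_noncanon_sites * len(noncanon_sites))
    regulatory = [(c, s - 2, e + 2) for c, s, e in noncanon_sites[:n_reg]]

    n_cons = round(conserved_frac_of_noncanon_sites * len(noncanon_sites))
    scores: dict[int, float] = {}
    for i, (c, s, e) in enumerate(noncanon_sites):
        val = 2.0 if i < n_cons else 0.0
        for p in range(s, e):
            scores[p] = val
    score_track = {chrom: scores}

    n_prom = round(promoter_fraction_of_peaks * n_peaks)
    promoters = [(p.chrom, p.start, p.end) for p in peaks[:n_prom]]
    prom_cats = categories[:n_prom]
    prom_nc = sum(1 for c in prom_cats if c in ("noncanon", "both"))
    prom_c = sum(1 for c in prom_cats if c in ("canon", "both"))
    prom_both = sum(1 for c in prom_cats if c == "both")
    prom_union = prom_nc + prom_c - prom_both

    manifest = {
        "seed": seed,
        "n_peaks": n_peaks,
        "peak_length": peak_length,
        "noncanon_word": noncanon_word,
        "canonical_word": canonical_word,
        "expected_peak_alone_fraction": n_nc / n_peaks,
        "expected_regulatory_fraction": (
            n_reg / len(noncanon_sites) if noncanon_sites else 0.0
        ),
        "n_noncanon_sites": len(noncanon_sites),
        "n_conserved_noncanon_sites": n_cons,
        "expected_promoter_jaccard": (
            prom_both / prom_union if prom_union else 0.0
        ),
    }
    return GenomeFixture(
        chrom=chrom, genome=genome, peaks=peaks, regulatory=regulatory,
        promoters=promoters, score_track=score_track, manifest=manifest,
    )
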