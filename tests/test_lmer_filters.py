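"""L-mer ledger filters: entropy, classification, RoR, alone occurrence."""

import math

import numpy as np
import pytest

from selexmotif._seq import canonical, reverse_complement
from selexmotif.lmer_filters import (
    FilterConfig, LmerRecord, PipelineAbort, alone_occurrence_census,
    classify_lmers, compute_enrichments, dinucleotide_entropy, entropy_floor,
    initial_lmer_records, ror_filter,
)
from selexmotif.selex_io import KmerTable, SelexRound, count_kmers


class TestDinucleotideEntropy:
    def test_homopolymer_zero(self):
        assert dinucleotide_entropy("AAAAAA") == 0.0

    def test_acac_closed_form(self):
        # dinucleotides of ACAC: AC, CA, AC -> {AC: 2/3, CA: 1/3}
        expected = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        assert dinucleotide_entropy("ACAC") == pytest.approx(expected)
        assert dinucleotide_entropy("ACAC") == pytest.approx(0.9183, abs=2e-4)

    def test_upper_bound(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=12))
            assert dinucleotide_entropy(seq) <= 4.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            dinucleotide_entropy("A")


class TestEntropyFloor:
    def test_min_includes_homopolymer(self):
        assert entropy_floor(["AAAA", "ACGT"]) == 0.0

    def test_single_match(self):
        assert entropy_floor(["ACGT"]) == dinucleotide_entropy("ACGT")

    def test_matches_bruteforce_min(self, rng):
        words = ["".join(rng.choice(list("ACGT"), size=8))
                 for _ in range(1000)]
        assert entropy_floor(words) == min(
            dinucleotide_entropy(w) for w in words
        )

    def test_no_matches_aborts(self):
        with pytest.raises(PipelineAbort):
            entropy_floor([])


class TestFilterConfig:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            FilterConfig(min_count=0)


def make_records(word_enrichments):
    recs = []
    for rank, (word, enr) in enumerate(
        sorted(word_enrichments.items(), key=lambda kv: -kv[1]), start=1
    ):
        recs.append(LmerRecord(word=canonical(word), count=200, entropy=2.0,
                               enrichment=enr, rank=rank))
    return recs


class TestClassify:
    def _round(self, oligos):
        return SelexRound(1, oligos, len(oligos[0]))

    def test_substring_containment(self):
        # match [10, 18), L-mer occurrence at [12, 18) -> motif
        oligo = "T" * 10 + "ACGTACGT" + "T" * 12
        word = canonical(oligo[12:18])
        recs = make_records({word: 5.0, "CCCGGG": 4.0})
        classify_lmers(recs, {0: [(10, 18)]}, self._round([oligo]), 6)
        by_word = {r.word: r for r in recs}
        assert by_word[word].klass == "motif"

    def test_superstring_containment(self):
        oligo = "T" * 12 + "ACGTAC" + "T" * 12
        word = canonical(oligo[10:20])
        recs = make_records({word: 5.0})
        classify_lmers(recs, {0: [(12, 18)]}, self._round([oligo]), 10)
        assert recs[0].klass == "motif"

    def test_partial_overlap_is_nonmotif(self):
        # L-mer window [8, 14) vs match [12, 18): neither contains the other
        oligo = "ACGGTCATTGCAACTGGATCCGTA"  # no repeated 6-mers
        word = canonical(oligo[8:14])
        other = canonical(oligo[12:18])
        recs = make_records({word: 6.0, other: 5.0})
        classify_lmers(recs, {0: [(12, 18)]}, self._round([oligo]), 6)
        by_word = {r.word: r for r in recs}
        assert by_word[other].klass == "motif"
        assert by_word[word].klass == "nonmotif"  # ties with cut survive

    def test_rank_cut_discards_below_lowest_motif(self):
        oligo = "T" * 10 + "ACGTAC" + "T" * 10
        motif_word = canonical("ACGTAC")
        recs = make_records({motif_word: 5.0, "AGAGAG": 6.0, "CTCCTC": 1.0})
        classify_lmers(recs, {0: [(10, 16)]}, self._round([oligo]), 6)
        by_word = {r.word: r for r in recs}
        assert by_word[motif_word].klass == "motif"
        assert by_word[canonical("AGAGAG")].klass == "nonmotif"
        assert by_word[canonical("CTCCTC")].klass == "discarded"

    def test_no_motif_lmers_aborts(self):
        recs = make_records({"ACACAC": 2.0})
        with pytest.raises(PipelineAbort):
            classify_lmers(recs, {}, self._round(["T" * 20]), 6)


class TestRor:
    def _tables(self, freq_by_round, word="ACGTAC"):
        tables = []
        total = 10_000
        from selexmotif._seq import word_to_code

        for f in freq_by_round:
            counts = {word_to_code(canonical(word)): int(f * total)}
            tables.append(KmerTable(k=6, counts=counts, total_positions=total))
        return tables

    def test_monotone_rise_passes(self):
        ok, ratios = ror_filter("ACGTAC", self._tables([0.001, 0.002, 0.003]))
        assert ok
        assert ratios == pytest.approx([2.0, 1.5])

    def test_dip_fails(self):
        ok, ratios = ror_filter("ACGTAC", self._tables([0.002, 0.001, 0.003]))
        assert not ok
        assert ratios[0] == pytest.approx(0.5)

    def test_absent_everywhere_fails(self):
        ok, _ = ror_filter("ACGTAC", self._tables([0.0, 0.0, 0.0]))
        assert not ok

    def test_appearance_passes_pair(self):
        ok, ratios = ror_filter("ACGTAC", self._tables([0.0, 0.002, 0.003]))
        assert ok
        assert ratios[0] == math.inf


class TestAloneCensus:
    def test_counts_match_bruteforce(self, rng):
        L = 6
        oligos = ["".join(rng.choice(list("ACGT"), size=20))
                  for _ in range(500)]
        rnd = SelexRound(1, oligos, 20)
        table = count_kmers(rnd, L)
        words = table.words(min_count=3)[:40]
        if len(words) < 4:
            pytest.skip("unlucky composition")
        recs = [LmerRecord(word=w, count=table.count(w), entropy=2.0,
                           enrichment=1.0, rank=i + 1)
                for i, w in enumerate(words)]
        motif_set = set(words[: len(words) // 2])
        for r in recs:
            r.klass = "motif" if r.word in motif_set else "nonmotif"
        alone_occurrence_census(recs, rnd, L)

        def occurs(word, oligo):
            return word in oligo or reverse_complement(word) in oligo

        for r in recs:
            if r.word in motif_set:
                continue
            oracle = sum(
                1 for o in oligos
                if occurs(r.word, o)
                and not any(occurs(m, o) for m in motif_set)
            )
            got = r.alone_oligos if r.alone_oligos is not None else 0
            assert got == oracle, r.word

    def test_word_alone_counted_and_cooccurring_not(self):
        motif, lone = "ACGTCA", "TTCGAA"
        oligos = [
            "G" * 5 + lone + "G" * 9,          # alone
            "G" * 3 + motif + lone + "G" * 5,  # co-occurs
        ]
        rnd = SelexRound(1, oligos, 20)
        recs = [
            LmerRecord(word=canonical(motif), count=100, entropy=2, enrichment=2,
                       rank=1, klass="motif"),
            LmerRecord(word=canonical(lone), count=100, entropy=2, enrichment=2,
                       rank=2, klass="nonmotif"),
        ]
        alone_occurrence_census(recs, rnd, 6)
        assert recs[1].alone_oligos == 1
        assert recs[1].klass == "nonmotif"


class TestInitialRecords:
    def test_count_and_entropy_filters(self, rng):
        oligos = ["A" * 20] * 200 + [
            "".join(rng.choice(list("ACGT"), size=20)) for _ in range(200)
        ]
        rnd = SelexRound(1, oligos, 20)
        table = count_kmers(rnd, 6)
        floor = dinucleotide_entropy("ACGTAC")
        records, audit = initial_lmer_records(table, floor, min_count=100)
        # the poly-A word passes the count filter but fails the entropy floor
        assert all(r.word != "AAAAAA" for r in records)
        assert audit["below_entropy_floor"] >= 1

    def test_enrichment_ranks_descending(self, rng):
        oligos = ["".join(rng.choice(list("ACGT"), size=20))
                  for _ in range(300)]
        rnd = SelexRound(1, oligos, 20)
        table = count_kmers(rnd, 2)
        records, _ = initial_lmer_records(table, 0.0, min_count=1)
        from selexmotif.markov_background import fit_markov

        compute_enrichments(records, table, fit_markov(oligos, 0))
        ranked = sorted(records, key=lambda r: r.rank)
        enr = [r.enrichment for r in ranked]
        assert enr == sorted(enr, reverse=True)
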