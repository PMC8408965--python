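"""Peak statistics, enrichment controls, shuffles, annotation overlap."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from selexmotif._seq import canonical, reverse_complement
from selexmotif.genomic_validation import (
    Peak, conservation_compare, count_occurrences, dinucleotide_shuffle,
    enrichment_shuffled_lmers, enrichment_vs_controls,
    make_dinuc_shuffled_controls, motif_occurs, peak_alone_fraction,
    promoter_comparison, promoter_jaccard, regulatory_fraction,
    validate_independent,
)
from selexmotif.lmer_clustering import ClusterHead, build_cluster
from selexmotif.selex_io import SelexRound


def word_cluster(word, kind="noncanonical"):
    head = ClusterHead(word=word[:8], l=min(8, len(word)), m=2)
    c = build_cluster(head, [canonical(word)])
    c.kind = kind
    return c


class TestMotifOccurs:
    def test_member_embedded(self):
        c = word_cluster("TTGGCCAA")
        found, intervals = motif_occurs(c, "GG" + "TTGGCCAA" + "GG")
        assert found
        assert intervals[0][:2] == (2, 10)

    def test_rc_embedded(self):
        c = word_cluster("TTGGCCTA")
        seq = "GG" + reverse_complement("TTGGCCTA") + "GG"
        found, intervals = motif_occurs(c, seq)
        assert found

    def test_absent(self):
        assert motif_occurs(word_cluster("TTGGCCAA"), "A" * 30)[0] is False


class TestPeakAloneFraction:
    def _peaks(self, seqs):
        return {"d0": [
            Peak(chrom="chr1", start=100 * i, end=100 * i + len(s),
                 dataset="d0", sequence=s) for i, s in enumerate(seqs)
        ]}

    def test_constructed_30_of_100(self):
        nc, cw = "TTGGCCAA", "ACGTCAGT"
        seqs = ([("G" * 6) + nc + ("G" * 6)] * 30
                + [("G" * 6) + cw + ("G" * 6)] * 50
                + ["G" * 20] * 20)
        frac, per = peak_alone_fraction(
            word_cluster(nc), [word_cluster(cw, "canonical")],
            self._peaks(seqs))
        assert frac == pytest.approx(0.30)

    def test_canonical_everywhere_zero(self):
        nc, cw = "TTGGCCAA", "ACGTCAGT"
        seqs = [("G" * 4) + cw + nc + ("G" * 4)] * 10
        frac, _ = peak_alone_fraction(
            word_cluster(nc), [word_cluster(cw, "canonical")],
            self._peaks(seqs))
        assert frac == 0.0

    def test_matches_bruteforce(self, rng):
        nc, cw = "TTGGCCAA", "ACGTCAGT"
        seqs = []
        for _ in range(200):
            s = "".join(rng.choice(list("ACGT"), size=60))
            r = rng.random()
            if r < 0.3:
                s = s[:20] + nc + s[28:]
            elif r < 0.6:
                s = s[:20] + cw + s[28:]
            seqs.append(s)
        nc_c = word_cluster(nc)
        cw_c = word_cluster(cw, "canonical")
        frac, _ = peak_alone_fraction(nc_c, [cw_c], self._peaks(seqs))

        def has(w, s):
            return w in s or reverse_complement(w) in s

        def cluster_has(c, s):
            return any(has(w, s) for w in c.member_words)

        oracle = sum(
            1 for s in seqs if cluster_has(nc_c, s) and not cluster_has(cw_c, s)
        ) / len(seqs)
        assert frac == pytest.approx(oracle)


class TestEnrichment:
    def _peaks(self, seqs):
        return {"d0": [Peak(chrom="c", start=0, end=len(s), dataset="d0",
                            sequence=s) for s in seqs]}

    def test_planted_vs_absent_shuffle_is_51(self, rng):
        # member occurs 50 times, its shuffle never: (50+1)/(0+1) = 51
        word = "AACCGGTT"
        c = word_cluster(word)
        seqs = ["T" * 4 + word + "T" * 4] * 50
        # find a seed whose shuffle is absent from the peaks (T-flanked)
        rep = enrichment_shuffled_lmers(c, self._peaks(seqs), seed=1)
        assert rep.e_m == pytest.approx(51.0)

    def test_homopolymer_member_contributes_one(self):
        c = word_cluster("AAAAAAAA")
        seqs = ["C" * 30] * 5
        rep = enrichment_shuffled_lmers(c, self._peaks(seqs), seed=0)
        assert rep.e_m == pytest.approx(1.0)

    def test_controls_identical_to_peaks_give_one(self):
        word = "AACCGGTT"
        c = word_cluster(word)
        seqs = ["T" * 4 + word + "T" * 4] * 20
        rep = enrichment_vs_controls(c, self._peaks(seqs), {"d0": seqs})
        assert rep.e_m == pytest.approx(1.0)

    def test_fixture_arithmetic(self):
        word = "AACCGGTT"
        c = word_cluster(word)
        seqs = ["T" * 4 + word + "T" * 4] * 50
        rep = enrichment_vs_controls(c, self._peaks(seqs), {"d0": ["T" * 16]})
        assert rep.e_m == pytest.approx(51.0)

    def test_null_dinuc_control_near_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=150))
                for _ in range(60)]
        peaks = self._peaks(seqs)
        controls = make_dinuc_shuffled_controls(peaks, seed=5)
        c = word_cluster("ACGTAC")
        rep = enrichment_vs_controls(c, peaks, controls)
        assert 0.5 < rep.e_m < 2.0


class TestDinucShuffle:
    def test_unique_arrangement_fixed(self, rng):
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"

    def test_dinucleotide_multiset_preserved(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            out = dinucleotide_shuffle(seq, rng)
            assert len(out) == len(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]
            orig = Counter(seq[i:i+2] for i in range(len(seq) - 1))
            got = Counter(out[i:i+2] for i in range(len(out) - 1))
            assert orig == got

    def test_all_eulerian_arrangements_appear(self, rng):
        seq = "ACATA"  # few valid arrangements
        seen = {dinucleotide_shuffle(seq, rng) for _ in range(2000)}
        target = Counter(seq[i:i+2] for i in range(len(seq) - 1))
        valid = {
            "".join(p)
            for p in itertools.permutations(seq)
            if p[0] == seq[0] and p[-1] == seq[-1]
            and Counter("".join(p)[i:i+2] for i in range(len(seq) - 1)) == target
        }
        assert seen == valid


class TestAnnotationOverlap:
    def test_all_inside(self):
        occ = [("chr1", 10, 18), ("chr1", 50, 58)]
        regions = [("chr1", 0, 100)]
        assert regulatory_fraction(occ, regions) == 1.0

    def test_disjoint(self):
        occ = [("chr1", 10, 18)]
        assert regulatory_fraction(occ, [("chr1", 50, 60)]) == 0.0
        assert regulatory_fraction(occ, [("chr2", 0, 100)]) == 0.0

    def test_matches_bruteforce(self, rng):
        occ = [("chr1", int(s), int(s) + 8)
               for s in rng.integers(0, 5000, size=1000)]
        regions = [("chr1", int(s), int(s) + int(rng.integers(5, 60)))
                   for s in rng.integers(0, 5000, size=80)]
        got = regulatory_fraction(occ, regions)
        oracle = sum(
            1 for c, s, e in occ
            if any(s < re and rs < e for rc, rs, re in regions if rc == c)
        ) / len(occ)
        assert got == pytest.approx(oracle)

    def test_invariant_to_bed_order(self, rng):
        occ = [("chr1", int(s), int(s) + 8)
               for s in rng.integers(0, 500, size=50)]
        regions = [("chr1", int(s), int(s) + 20)
                   for s in rng.integers(0, 500, size=10)]
        assert regulatory_fraction(occ, regions) == regulatory_fraction(
            occ, regions[::-1]
        )


class TestPromoterJaccard:
    def test_identical(self):
        assert promoter_jaccard({1, 2}, {1, 2}) == 1.0

    def test_disjoint(self):
        assert promoter_jaccard({1}, {2}) == 0.0

    def test_arithmetic(self):
        assert promoter_jaccard({1, 2, 3}, {3, 4, 5, 6}) == pytest.approx(1 / 6)

    def test_both_empty_defined_zero(self):
        assert promoter_jaccard(set(), set()) == 0.0

    def test_ten_percent_gate(self):
        promoters = [("chr1", 0, 100)]
        nc = [("chr1", 10, 18)] + [("chr2", 0, 8)] * 19  # 5% in promoters
        cn = [("chr1", 20, 28)]
        j, frac_nc, frac_c = promoter_comparison(nc, cn, promoters)
        assert j is None
        assert frac_nc == pytest.approx(0.05)


class TestConservation:
    def test_identical_groups_zero_statistic(self):
        stat, p = conservation_compare([1.0] * 20, [1.0] * 20)
        assert stat == 0.0

    def test_disjoint_groups_statistic_one(self):
        stat, p = conservation_compare([0.0] * 20, [1.0] * 20)
        assert stat == 1.0
        assert p < 0.01

    def test_matches_ecdf_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(10, 40)))
            b = rng.normal(0.3, 1.2, size=int(rng.integers(10, 40)))
            stat, _ = conservation_compare(a, b)
            grid = np.concatenate([a, b])
            gap = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in grid
            )
            assert stat == pytest.approx(gap)


class TestValidateIndependent:
    def test_no_survivors_returns_none(self, rng):
        word = "TTGGCCAA"
        c = word_cluster(word)
        oligos = ["".join(rng.choice(list("ACGT"), size=30))
                  for _ in range(300)]
        r0 = SelexRound(0, oligos, 30)
        # "selected" round with the word strictly depleted
        kept = [o for o in oligos
                if word not in o and reverse_complement(word) not in o]
        r1 = SelexRound(1, (kept * 3)[: len(oligos)], 30)
        assert validate_independent(c, r0, r1) is None

    def test_planted_word_revalidates(self, rng):
        word = "TTGGCCAA"
        c = word_cluster(word)
        background = ["".join(rng.choice(list("ACGT"), size=30))
                      for _ in range(200)]
        planted = [o[:10] + word + o[18:] for o in background[:80]]
        r0 = SelexRound(0, background, 30)
        r1 = SelexRound(1, planted + background[80:120], 30)
        result = validate_independent(c, r0, r1)
        assert result is not None
        pwm, dist = result
        assert dist < 0.1
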