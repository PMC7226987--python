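"""Motif scanning: IUPAC expansion, oracle equivalence, PWM thresholds, shuffles."""

from __future__ import annotations

import itertools
import re
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from puregulon import (
    TranscriptRecord,
    dinucleotide_shuffle,
    discover_words,
    expand_iupac,
    motif_set_stats,
    pwm_from_iupac,
    region_distribution,
    scan_iupac,
    scan_pwm,
)
from puregulon.motifs import (
    BASES,
    IUPAC_CODES,
    MotifHit,
    PwmScorer,
    attribute_regions,
    classic_pbe_words,
    degenerate_pbe_words,
    has_classic_pbe,
    has_degenerate_pbe,
)


def regex_scan_oracle(seq: str, motif: str) -> list[int]:
    """Independent reference: regex with lookahead for overlapping matches."""
    pattern = "".join(f"[{IUPAC_CODES[c]}]" for c in motif.upper())
    return [m.start() for m in re.finditer(f"(?=({pattern}))", seq)]


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestExpandIupac:
    def test_pbe_expands_to_six_words(self):
        words = expand_iupac("UGUAHAUW")
        assert words == {"UGUAAAUA", "UGUAAAUU", "UGUACAUA",
                         "UGUACAUU", "UGUAUAUA", "UGUAUAUU"}

    @pytest.mark.parametrize("motif,count", [("UGUANAUA", 4), ("ACGU", 1), ("NN", 16)])
    def test_expansion_counts(self, motif, count):
        assert len(expand_iupac(motif)) == count

    def test_concrete_word_is_identity(self):
        assert expand_iupac("ACGU") == {"ACGU"}

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            expand_iupac("UGXA")


class TestScanIupac:
    def test_single_embedded_pbe(self):
        hits = scan_iupac("AAUGUAAAUAUU", "UGUAHAUW")
        assert [(h.start, h.width) for h in hits] == [(2, 8)]

    def test_homopolymer_has_no_hits(self):
        assert scan_iupac("A" * 1000, "UGUAHAUW") == []

    def test_t_and_u_are_equivalent(self):
        rna = scan_iupac("AAUGUAAAUAUU", "UGUAHAUW")
        dna = scan_iupac("AATGTAAATATT", "TGTAHATW")
        assert [h.start for h in rna] == [h.start for h in dna]

    def test_overlapping_vs_nonoverlapping(self):
        seq = "ACACACAC"
        assert [h.start for h in scan_iupac(seq, "ACAC")] == [0, 2, 4]
        assert [h.start for h in scan_iupac(seq, "ACAC", count_overlaps=False)] == [0, 4]

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        for motif in ("UGUAHAUW", "YGCY", "CACNNCAC"):
            for _ in range(30):
                seq = random_seq(rng, 2000)
                got = [h.start for h in scan_iupac(seq, motif)]
                assert got == regex_scan_oracle(seq, motif)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGU", min_size=0, max_size=60),
           motif=st.text(alphabet="ACGURYSWKMBDHVN", min_size=1, max_size=6))
    def test_regex_oracle_equivalence_property(self, seq, motif):
        assert [h.start for h in scan_iupac(seq, motif)] == regex_scan_oracle(seq, motif)


class TestPwmThreshold:
    @pytest.mark.parametrize("iupac", ["UGUANAUA", "UGUAHAUW"])
    @pytest.mark.parametrize("p", [0.5, 0.05, 0.01, 0.001])
    def test_threshold_matches_exhaustive_enumeration(self, iupac, p):
        scorer = PwmScorer(pwm_from_iupac(iupac))
        counts = Counter(scorer.score_int("".join(w))
                         for w in itertools.product(BASES, repeat=8))
        tail = Fraction(0)
        expected = None
        for s in sorted(counts, reverse=True):
            tail += Fraction(counts[s], 4 ** 8)
            if tail <= Fraction(p).limit_denominator(10**12):
                expected = s
            else:
                break
        assert scorer.threshold_int_from_pvalue(p) == expected

    def test_random_pwm_threshold_matches_enumeration(self, rng):
        pwm = rng.dirichlet(np.ones(4), size=6)
        scorer = PwmScorer(pwm)
        scores = sorted((scorer.score_int("".join(w))
                         for w in itertools.product(BASES, repeat=6)), reverse=True)
        t = scorer.threshold_int_from_pvalue(0.01)
        tail = sum(1 for s in scores if s >= t) / 4 ** 6
        assert tail <= 0.01
        next_lower = max((s for s in scores if s < t), default=None)
        if next_lower is not None:
            assert sum(1 for s in scores if s >= next_lower) / 4 ** 6 > 0.01

    def test_p_of_one_gives_minimum_achievable_score(self):
        scorer = PwmScorer(pwm_from_iupac("UGUANAUA"))
        scores = [scorer.score_int("".join(w)) for w in itertools.product(BASES, repeat=8)]
        assert scorer.threshold_int_from_pvalue(1.0) == min(scores)

    def test_tiny_p_still_passes_consensus(self):
        scorer = PwmScorer(pwm_from_iupac("ACGUACGU"))
        t = scorer.threshold_int_from_pvalue(1e-9)  # < 4^-8
        assert scorer.score_int("ACGUACGU") >= t
        hits = scorer.scan("ACGUACGU", t * scorer.granularity)
        assert len(hits) == 1

    def test_threshold_monotone_in_p(self):
        scorer = PwmScorer(pwm_from_iupac("UGUAHAUW"))
        ts = [scorer.threshold_int_from_pvalue(p) for p in (0.5, 0.1, 0.01, 0.001, 1e-4)]
        assert ts == sorted(ts)


class TestScanPwm:
    def test_consensus_embedded_once(self):
        pwm = pwm_from_iupac("UGUAAAUA")
        t = PwmScorer(pwm).threshold_from_pvalue(0.001)
        hits = scan_pwm("CCCCUGUAAAUACCCC", pwm, t)
        assert [h.start for h in hits] == [4]
        assert hits[0].score is not None

    def test_infinite_threshold_gives_no_hits(self):
        pwm = pwm_from_iupac("UGUAAAUA")
        assert scan_pwm("CCCCUGUAAAUACCCC", pwm, float("inf")) == []

    def test_matches_bruteforce_window_oracle(self, rng):
        pwm = rng.dirichlet(np.ones(4), size=5)
        scorer = PwmScorer(pwm)
        t = scorer.threshold_from_pvalue(0.05)
        seq = random_seq(rng, 3000)
        got = {h.start for h in scorer.scan(seq, t)}
        t_int = round(t / scorer.granularity)
        expected = {i for i in range(len(seq) - 4)
                    if scorer.score_int(seq[i:i + 5]) >= t_int}
        assert got == expected


class TestRegions:
    def make_record(self):
        return TranscriptRecord(gene="g", sequence="A" * 100,
                                utr5_len=20, cds_len=60, utr3_len=20)

    def test_one_hit_per_region_is_a_third_each(self):
        rec = self.make_record()
        hits = [MotifHit(gene="g", start=s, width=4) for s in (0, 20, 80)]
        hits = attribute_regions(hits, rec)
        pct = region_distribution(hits)
        assert pct == pytest.approx((100 / 3,) * 3)
        assert sum(pct) == pytest.approx(100.0)

    def test_all_hits_in_utr3(self):
        rec = self.make_record()
        hits = attribute_regions([MotifHit("g", 85, 4), MotifHit("g", 90, 4)], rec)
        assert region_distribution(hits) == (0.0, 0.0, 100.0)

    def test_boundary_hit_attributed_by_start(self):
        rec = self.make_record()
        (hit,) = attribute_regions([MotifHit("g", 18, 8)], rec)  # spans utr5/cds
        assert hit.region == "utr5"

    def test_no_hits_is_an_error(self):
        with pytest.raises(ValueError, match="no hits"):
            region_distribution([])

    def test_planted_utr3_bias_recovered(self, study_records, study_truth):
        """PBE planting in bound 3'UTRs dominates the regional distribution."""
        bound = [r for r in study_records if study_truth.bound_by[r.gene] != "none"]
        stats = motif_set_stats(bound, "UGUAHAUW")
        assert stats.region_pct[2] > 80.0


class TestMotifSetStats:
    def test_mean_and_fraction(self):
        recs = [
            TranscriptRecord("a", "CCUGUAAAUACCUGUAAAUACC", 2, 10, 10),
            TranscriptRecord("b", "C" * 22, 2, 10, 10),
        ]
        stats = motif_set_stats(recs, "UGUAHAUW")
        assert stats.mean_hits_per_sequence == 1.0
        assert stats.frac_with_at_least_one == 0.5
        assert stats.per_gene_counts == {"a": 2, "b": 0}

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            motif_set_stats([], "UGUAHAUW")

    def test_top_n_restriction_uses_ranking(self):
        recs = [
            TranscriptRecord("hi", "CCUGUAAAUACC", 2, 5, 5),
            TranscriptRecord("lo", "C" * 12, 2, 5, 5),
        ]
        stats = motif_set_stats(recs, "UGUAHAUW", top_n=1, ranking={"hi": 9.0, "lo": 1.0})
        assert stats.n_sequences == 1
        assert stats.mean_hits_per_sequence == 1.0

    def test_planted_rate_recovered_within_3_se(self, study_records, study_truth, study_config):
        bound = [r for r in study_records if study_truth.bound_by[r.gene] != "none"]
        stats = motif_set_stats(bound, "UGUAHAUW")
        planted = np.array([study_truth.planted_pbe[r.gene][2] for r in bound])
        # observed = planted + chance occurrences, so at least the planted mean
        rate = study_config.motif_rate_bound
        se = np.sqrt(rate / len(bound))
        assert stats.mean_hits_per_sequence >= planted.mean() - 1e-9
        assert abs(planted.mean() - rate) < 3 * se


class TestDinucleotideShuffle:
    def test_unique_arrangement_is_fixed(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_dinucleotide_counts_preserved(self, seed, rng):
        seq = random_seq(rng, 500)
        shuffled = dinucleotide_shuffle(seq, seed=seed)
        assert len(shuffled) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))

    def test_distinct_seeds_give_distinct_valid_shuffles(self):
        seq = "ACGUACGUACGUACGUGGCCAAUU"
        s1 = dinucleotide_shuffle(seq, seed=1)
        s2 = dinucleotide_shuffle(seq, seed=5)
        for s in (s1, s2):
            assert Counter(zip(seq, seq[1:])) == Counter(zip(s, s[1:]))
        assert s1 != s2

    def test_deterministic_per_seed(self):
        seq = "ACGUACGUGGCCAAUUACGU"
        assert dinucleotide_shuffle(seq, 7) == dinucleotide_shuffle(seq, 7)


class TestDiscoverWords:
    def test_planted_word_ranks_first(self, rng):
        word = "UGUAAAUA"
        pos, neg = [], []
        for i in range(100):
            s = random_seq(rng, 200)
            if i < 80:
                s = s[:50] + word + s[58:]
            pos.append(s)
        for i in range(100):
            s = random_seq(rng, 200)
            if i < 5:
                s = s[:50] + word + s[58:]
            neg.append(s)
        table = discover_words(pos, neg, width=8)
        assert table.iloc[0]["word"] == word
        assert table.iloc[0]["q"] < 0.05

    def test_null_comparison_has_no_fdr_hits(self, rng):
        seqs = [random_seq(rng, 150) for _ in range(60)]
        table = discover_words(seqs, seqs, width=6)
        assert (table["q"] >= 0.05).all()

    def test_width_longer_than_shortest_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="width"):
            discover_words(["ACGUACGU"], ["ACG"], width=8)


class TestDegeneratePbe:
    def test_classic_words_are_not_degenerate(self):
        assert classic_pbe_words() & degenerate_pbe_words() == set()

    def test_degenerate_words_keep_ugua_core_and_distance_one(self):
        classic_tails = {w[4:] for w in classic_pbe_words()}
        for w in degenerate_pbe_words():
            assert w.startswith("UGUA")
            dists = [sum(a != b for a, b in zip(w[4:], t)) for t in classic_tails]
            assert min(dists) == 1

    def test_sequence_classification(self):
        assert has_classic_pbe("CCUGUAAAUACC")
        assert not has_classic_pbe("CCUGUAGAUACC")
        assert has_degenerate_pbe("CCUGUAGAUACC")  # G at position 5, UGUA core
        assert not has_degenerate_pbe("C" * 20)
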