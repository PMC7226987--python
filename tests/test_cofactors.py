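"""Interactor calling, cofactor-motif enrichment, term enrichment, regulon."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from puregulon import (
    MotifDefinition,
    TranscriptRecord,
    build_negative_set,
    build_regulon,
    call_interactors,
    cofactor_enrichment,
    length_correction_coefficient,
    term_enrichment,
)
from puregulon import simulate as sim
from puregulon.cofactors import CofactorEnrichment, InteractorCall, TermEnrichmentResult


def presence(rows: dict[str, list[int]], prefix="x") -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    df.columns = [f"{prefix}_rep{i + 1}" for i in range(df.shape[1])]
    return df


def ms_inputs(pum1, pum2, igg):
    """Convenience: same matrix used for both RNase conditions."""
    return ({"minus": pum1, "plus": pum1}, {"minus": pum2, "plus": pum2},
            {"minus": igg, "plus": igg})


class TestCallInteractors:
    def test_full_bait_and_empty_igg_is_called(self):
        p1 = presence({"A": [1, 1, 1], "B": [1, 1, 0]})
        p2 = presence({"A": [0, 0, 0], "B": [0, 0, 0]})
        igg = presence({"A": [0, 0, 0], "B": [0, 0, 0]})
        calls = call_interactors(*ms_inputs(p1, p2, igg))
        assert [c.protein for c in calls] == ["A"]
        assert calls[0].bait == "PUM1" and calls[0].rna_dependence == "both"

    def test_two_of_three_replicates_is_not_called(self):
        p = presence({"B": [1, 1, 0]})
        z = presence({"B": [0, 0, 0]})
        assert call_interactors(*ms_inputs(p, z, z)) == []

    def test_igg_detection_vetoes_the_call(self):
        p = presence({"A": [1, 1, 1]})
        z = presence({"A": [0, 0, 0]})
        igg = presence({"A": [0, 1, 0]})
        assert call_interactors(*ms_inputs(p, z, igg)) == []

    def test_adding_igg_detections_only_removes_calls(self, rng):
        """Monotonicity: calls under noisier IgG are a subset."""
        mat = (rng.random((30, 3)) < 0.6).astype(int)
        p1 = presence({f"P{i}": list(mat[i]) for i in range(30)})
        z = presence({f"P{i}": [0, 0, 0] for i in range(30)})
        base = {c.protein for c in call_interactors(*ms_inputs(p1, z, z))}
        noisy_igg = presence({f"P{i}": list((rng.random(3) < 0.3).astype(int))
                              for i in range(30)})
        noisy = {c.protein for c in call_interactors(*ms_inputs(p1, z, noisy_igg))}
        assert noisy <= base

    def test_rna_dependence_classes(self):
        p1_minus = presence({"DEP": [1, 1, 1], "IND": [0, 0, 0], "BOTH": [1, 1, 1]})
        p1_plus = presence({"DEP": [0, 0, 0], "IND": [1, 1, 1], "BOTH": [1, 1, 1]})
        z = presence({"DEP": [0, 0, 0], "IND": [0, 0, 0], "BOTH": [0, 0, 0]})
        calls = {c.protein: c for c in call_interactors(
            {"minus": p1_minus, "plus": p1_plus}, {"minus": z, "plus": z},
            {"minus": z, "plus": z})}
        assert calls["DEP"].rna_dependence == "dependent"
        assert calls["IND"].rna_dependence == "independent"
        assert calls["BOTH"].rna_dependence == "both"

    def test_exact_recovery_from_noise_free_simulation(self):
        config = sim.SyntheticConfig(seed=21, n_genes=50, ms_igg_noise_rate=0.0,
                                     ms_detection_dropout=0.0)
        _, truth = sim.generate_transcriptome(config)
        tables = sim.generate_ms_tables(config, truth)
        calls = call_interactors(
            {"minus": tables["PUM1_IP_minus"], "plus": tables["PUM1_IP_plus"]},
            {"minus": tables["PUM2_IP_minus"], "plus": tables["PUM2_IP_plus"]},
            {"minus": tables["IgG_minus"], "plus": tables["IgG_plus"]},
        )
        by_protein = {c.protein: c for c in calls}
        true_interactors = {p for p in truth.proteins if truth.interactor_of[p] != "none"}
        assert set(by_protein) == true_interactors
        for p, c in by_protein.items():
            assert c.bait == truth.interactor_of[p]
            expected = "dependent" if truth.rna_dependent[p] else "both"
            assert c.rna_dependence == expected


class TestNegativeSetAndLengthCorrection:
    def make_candidates(self):
        return [TranscriptRecord(f"n{i}", "A" * (100 + 10 * i), 10, 50, 40 + 10 * i)
                for i in range(10)]

    def test_window_excluding_everything_is_an_error(self):
        with pytest.raises(ValueError, match="length-matched"):
            build_negative_set(self.make_candidates(), [100], (1000, 2000))

    def test_window_covering_all_keeps_all(self):
        cands = self.make_candidates()
        negs, report = build_negative_set(cands, [150], (0, float("inf")))
        assert negs == cands
        assert report["n_negatives"] == 10

    def test_seeded_sampling_is_reproducible(self):
        cands = self.make_candidates()
        n1, _ = build_negative_set(cands, [150], (0, 1e9), n=4, seed=5)
        n2, _ = build_negative_set(cands, [150], (0, 1e9), n=4, seed=5)
        assert n1 == n2 and len(n1) == 4

    def test_published_style_mean_lengths(self):
        # mean lengths as printed for regulated targets vs negatives
        c = length_correction_coefficient([4817], [4177])
        assert c == pytest.approx(4817 / 4177)
        assert c == pytest.approx(1.1532, abs=2e-4)

    def test_equal_means_give_unity(self):
        assert length_correction_coefficient([100, 200], [150, 150]) == pytest.approx(1.0)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            length_correction_coefficient([], [100])


def seq_with_hits(word: str, n_hits: int, length: int) -> str:
    """A C-homopolymer with n spaced copies of ``word`` embedded."""
    s = list("C" * length)
    w = len(word)
    for k in range(n_hits):
        start = k * (w + 3)
        s[start:start + w] = word
    return "".join(s)


class TestCofactorEnrichment:
    MOTIF = MotifDefinition(name="RBPX", kind="iupac", iupac="ACGUACGU")

    def test_ratio_arithmetic(self):
        # target rate 2.0/seq over mean length 1000; negative rate 0.8/seq
        # over mean length 800 => c = 1.25 and ratio = 2.0 / (0.8 * 1.25) = 2.0
        targets = [TranscriptRecord(f"t{i}", seq_with_hits("ACGUACGU", 2, 1000), 100, 500, 400)
                   for i in range(2)]
        negatives = [TranscriptRecord(f"n{i}", seq_with_hits("ACGUACGU", 1 if i < 4 else 0, 800),
                                      100, 400, 300) for i in range(5)]
        enr = cofactor_enrichment(targets, negatives, self.MOTIF)
        assert enr.target_rate == pytest.approx(2.0)
        assert enr.negative_rate == pytest.approx(0.8)
        assert enr.length_coefficient == pytest.approx(1.25)
        assert enr.enrichment_ratio == pytest.approx(2.0)

    def test_absent_motif_gives_zero_ratio_with_note(self):
        targets = [TranscriptRecord("t", "C" * 100, 10, 50, 40)]
        negatives = [TranscriptRecord("n", "C" * 100, 10, 50, 40)]
        enr = cofactor_enrichment(targets, negatives, self.MOTIF)
        assert enr.enrichment_ratio == 0.0 and "absent" in enr.note

    def test_selection_is_strictly_above_mean(self):
        targets = [
            TranscriptRecord("hi", seq_with_hits("ACGUACGU", 3, 500), 50, 250, 200),
            TranscriptRecord("lo", seq_with_hits("ACGUACGU", 1, 500), 50, 250, 200),
        ]
        negatives = [TranscriptRecord("n", seq_with_hits("ACGUACGU", 1, 500), 50, 250, 200)]
        enr = cofactor_enrichment(targets, negatives, self.MOTIF)
        assert enr.selected_genes == ["hi"]  # mean is 2; ties would be excluded
        tied = [TranscriptRecord("a", seq_with_hits("ACGUACGU", 2, 500), 50, 250, 200),
                TranscriptRecord("b", seq_with_hits("ACGUACGU", 2, 500), 50, 250, 200)]
        assert cofactor_enrichment(tied, negatives, self.MOTIF).selected_genes == []

    def test_ratio_invariant_to_duplicating_negatives(self):
        targets = [TranscriptRecord("t", seq_with_hits("ACGUACGU", 2, 600), 50, 350, 200)]
        negatives = [TranscriptRecord(f"n{i}", seq_with_hits("ACGUACGU", 1, 500), 50, 250, 200)
                     for i in range(3)]
        doubled = negatives + [TranscriptRecord(f"m{i}", r.sequence, 50, 250, 200)
                               for i, r in enumerate(negatives)]
        e1 = cofactor_enrichment(targets, negatives, self.MOTIF)
        e2 = cofactor_enrichment(targets, doubled, self.MOTIF)
        assert e1.enrichment_ratio == pytest.approx(e2.enrichment_ratio)

    def test_planted_bias_recovered_from_simulation(self, study_by_gene, study_truth):
        regulated = [study_by_gene[g] for g in sorted(study_truth.regulated_set("PUM1"))]
        negatives = [study_by_gene[g] for g in study_truth.genes
                     if study_truth.bound_by[g] == "none"
                     and study_truth.regulated_by[g] == "none"]
        planted = MotifDefinition(name="IGF2BP1", kind="iupac", iupac="CAUCAUC")
        control = MotifDefinition(name="MBNL1", kind="iupac", iupac="YGCY")
        e_planted = cofactor_enrichment(regulated, negatives, planted)
        e_control = cofactor_enrichment(regulated, negatives, control)
        assert e_planted.enrichment_ratio > 5.0
        assert 0.8 < e_control.enrichment_ratio < 1.25


def exact_hypergeom_tail(k, N, K, n) -> float:
    """Independent oracle: exact combinatorial upper tail as a Fraction."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


class TestTermEnrichment:
    def test_matches_exact_combinatorial_tail(self):
        background = {f"g{i}" for i in range(100)}
        term_genes = {f"g{i}" for i in range(10)}
        subset = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        (res,) = term_enrichment(subset, background, {"T": term_genes})
        assert res.k == 5 and res.K == 10 and res.N == 100 and res.n_subset == 10
        assert res.p == pytest.approx(exact_hypergeom_tail(5, 100, 10, 10), abs=1e-12)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(20):
            N = int(rng.integers(20, 200))
            K = int(rng.integers(3, N))
            n = int(rng.integers(1, N))
            background = {f"g{i}" for i in range(N)}
            term_genes = {f"g{i}" for i in range(K)}
            subset = set(rng.choice(sorted(background), size=n, replace=False))
            (res,) = term_enrichment(subset, background, {"T": term_genes})
            assert res.p == pytest.approx(exact_hypergeom_tail(res.k, N, K, n), abs=1e-12)

    def test_small_overlap_fails_min_genes_filter(self):
        background = {f"g{i}" for i in range(50)}
        term_genes = {"g0", "g1", "g2", "g3"}
        subset = {"g0", "g1", "g40"}
        (res,) = term_enrichment(subset, background, {"T": term_genes})
        assert res.k == 2 and not res.passes

    def test_subset_equal_to_background_gives_p_one(self):
        background = {f"g{i}" for i in range(30)}
        sets = {"T1": {f"g{i}" for i in range(10)}, "T2": {f"g{i}" for i in range(5, 20)}}
        for res in term_enrichment(background, background, sets):
            assert res.p == pytest.approx(1.0)

    def test_bonferroni_over_tested_terms_only(self):
        background = {f"g{i}" for i in range(50)}
        sets = {"big": {f"g{i}" for i in range(10)},
                "tiny": {"g0", "g1"}}  # K=2 < min_genes: not tested
        results = term_enrichment({"g0", "g1", "g2", "g3"}, background, sets)
        assert [r.term for r in results] == ["big"]
        assert results[0].p_bonf == pytest.approx(min(1.0, results[0].p))


class TestBuildRegulon:
    def interactor(self):
        return InteractorCall(protein="RBP1", bait="PUM1", rna_dependence="independent")

    def enrichment(self, ratio=5.0):
        return CofactorEnrichment(rbp="RBP1", motif="ACGU", target_rate=2.0,
                                  negative_rate=0.4, length_coefficient=1.0,
                                  enrichment_ratio=ratio, selected_genes=["g1"])

    def passing_term(self):
        return TermEnrichmentResult(term="processX", k=5, n_subset=10, K=8, N=100,
                                    p=1e-6, p_bonf=1e-5, passes=True)

    def test_no_passing_terms_leaves_interaction_edges_only(self):
        g = build_regulon([self.interactor()], {("PUM1", "RBP1"): self.enrichment()}, {})
        kinds = {d["kind"] for _, _, d in g.edges(data=True)}
        assert kinds == {"interaction_rna_independent"}

    def test_one_rbp_one_passing_term(self):
        g = build_regulon([self.interactor()],
                          {("PUM1", "RBP1"): self.enrichment()},
                          {("PUM1", "RBP1"): [self.passing_term()]})
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.nodes["processX"]["kind"] == "term"

    def test_ratio_below_threshold_blocks_coregulation(self):
        g = build_regulon([self.interactor()],
                          {("PUM1", "RBP1"): self.enrichment(ratio=1.5)},
                          {("PUM1", "RBP1"): [self.passing_term()]},
                          ratio_threshold=2.0)
        assert not any(d["kind"] == "coregulation" for _, _, d in g.edges(data=True))

    def test_noninteractor_rbp_gets_no_coregulation_edge(self):
        g = build_regulon([], {("PUM1", "RBP1"): self.enrichment()},
                          {("PUM1", "RBP1"): [self.passing_term()]})
        assert g.number_of_edges() == 0
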