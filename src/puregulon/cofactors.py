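"""PUM-interacting proteins, cofactor-motif co-occurrence, and the regulon graph.

An interactor is a protein detected in every bait replicate and in no IgG
replicate of the same (+-RNase) condition; comparing the two conditions
classifies the interaction as RNA-dependent (lost upon RNase treatment),
RNA-independent, or present in both.

Cofactor-motif enrichment compares hits-per-sequence of an RBP's binding
motif between regulated targets and length-matched negative transcripts
(neither bound nor knockdown-responsive), with a multiplicative
length-correction coefficient c = mean_length(targets) / mean_length(
negatives) applied to the negative rate; enrichment of the negative set is
thereby set to 1. The genes driving an enriched pair are the regulated
transcripts whose per-sequence hit count strictly exceeds the mean over the
regulated set ("greater-than-average"). Those subsets feed a hypergeometric
term-enrichment with Bonferroni correction and ClueGO-style filters
(>= 3 genes in term, >= 4% of the subset), and the surviving PUM -> RBP ->
term structure is assembled into the regulon graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import MotifDefinition, TranscriptRecord
from .motifs import count_motif_hits

logger = logging.getLogger(__name__)


@dataclass
class InteractorCall:
    """One protein called as a PUM interactor."""

    protein: str
    bait: str            # PUM1 | PUM2 | both
    rna_dependence: str  # dependent | independent | both


def _called(bait_table: pd.DataFrame, igg_table: pd.DataFrame) -> set[str]:
    """Proteins present in all bait replicates and absent from all IgG replicates."""
    if not bait_table.index.equals(igg_table.index):
        raise ValueError("bait and IgG tables must share the same protein index")
    all_bait = bait_table.eq(1).all(axis=1)
    no_igg = igg_table.eq(0).all(axis=1)
    return set(bait_table.index[all_bait & no_igg])


def call_interactors(
    pum1_tables: Mapping[str, pd.DataFrame],
    pum2_tables: Mapping[str, pd.DataFrame],
    igg_tables: Mapping[str, pd.DataFrame],
) -> list[InteractorCall]:
    """Call interactors from presence matrices keyed 'minus' / 'plus' (RNase).

    Per bait and condition, a protein is called iff detected in every bait
    replicate and in zero IgG replicates. RNA dependence per protein:
    'dependent' if called without RNase only, 'independent' if called with
    RNase only, 'both' if called under both conditions. Proteins called for
    both baits are reported with bait='both'.
    """
    for tabs, label in ((pum1_tables, "PUM1"), (pum2_tables, "PUM2"), (igg_tables, "IgG")):
        missing = {"minus", "plus"} - set(tabs)
        if missing:
            raise ValueError(f"{label} tables lack conditions {sorted(missing)}")
    by_bait: dict[str, dict[str, set[str]]] = {}
    for bait, tabs in (("PUM1", pum1_tables), ("PUM2", pum2_tables)):
        by_bait[bait] = {cond: _called(tabs[cond], igg_tables[cond]) for cond in ("minus", "plus")}
    calls = []
    proteins = set().union(*(s for d in by_bait.values() for s in d.values()))
    for p in sorted(proteins):
        baits = [b for b in ("PUM1", "PUM2")
                 if p in by_bait[b]["minus"] or p in by_bait[b]["plus"]]
        in_minus = any(p in by_bait[b]["minus"] for b in baits)
        in_plus = any(p in by_bait[b]["plus"] for b in baits)
        dependence = "both" if (in_minus and in_plus) else ("dependent" if in_minus else "independent")
        calls.append(InteractorCall(
            protein=p,
            bait="both" if len(baits) == 2 else baits[0],
            rna_dependence=dependence,
        ))
    return calls


# ---------------------------------------------------------------------------
# Negative sets and length correction
# ---------------------------------------------------------------------------

def build_negative_set(
    candidates: Sequence[TranscriptRecord],
    target_lengths: Sequence[int],
    length_window: tuple[float, float],
    n: int | None = None,
    seed: int | None = None,
) -> tuple[list[TranscriptRecord], dict]:
    """Select negative transcripts with lengths inside ``length_window``.

    ``candidates`` must already be restricted to genes neither bound nor
    knockdown-responsive. If ``n`` is given, that many negatives are
    sampled reproducibly with ``seed``; otherwise all in-window candidates
    are used. Returns the negatives and a report with mean/range of both
    sets.
    """
    lo, hi = length_window
    in_window = [r for r in candidates if lo <= len(r) <= hi]
    if not in_window:
        raise ValueError(f"no length-matched negatives in window [{lo}, {hi}]")
    if n is not None and n < len(in_window):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(in_window), size=n, replace=False)
        in_window = [in_window[i] for i in sorted(idx)]
    neg_lengths = [len(r) for r in in_window]
    report = {
        "n_negatives": len(in_window),
        "negative_mean_length": float(np.mean(neg_lengths)),
        "negative_length_range": (min(neg_lengths), max(neg_lengths)),
        "target_mean_length": float(np.mean(target_lengths)),
        "target_length_range": (int(min(target_lengths)), int(max(target_lengths))),
    }
    return in_window, report


def length_correction_coefficient(targets, negatives) -> float:
    """c = mean_length(targets) / mean_length(negatives).

    Accepts transcript records or raw lengths. Applied multiplicatively to
    the negative per-sequence hit rate so slightly shorter negatives are
    not mistaken for motif depletion.
    """
    t = [len(x) if not isinstance(x, (int, float)) else x for x in targets]
    n = [len(x) if not isinstance(x, (int, float)) else x for x in negatives]
    if not t or not n:
        raise ValueError("empty transcript set")
    c = float(np.mean(t)) / float(np.mean(n))
    if c <= 0:
        raise ValueError("length-correction coefficient must be positive")
    return c


@dataclass
class CofactorEnrichment:
    """Co-occurrence enrichment of one RBP motif in a regulated target set."""

    rbp: str
    motif: str
    target_rate: float
    negative_rate: float
    length_coefficient: float
    enrichment_ratio: float
    selected_genes: list[str] = field(default_factory=list)
    note: str = ""


def cofactor_enrichment(
    regulated_transcripts: Sequence[TranscriptRecord],
    negative_transcripts: Sequence[TranscriptRecord],
    rbp_motif: MotifDefinition,
    pvalue: float = 0.01,
    length_correction: str = "mean_ratio",
    background: Sequence[float] | None = None,
) -> CofactorEnrichment:
    """Motif co-occurrence enrichment of ``rbp_motif`` in regulated targets.

    Hits are counted at FIMO-style p < ``pvalue`` for PWMs (exact matching
    for IUPAC motifs). With ``length_correction='mean_ratio'`` the ratio is
    target_rate / (negative_rate * c); with ``'per_nt'`` both rates are per
    nucleotide and no coefficient is applied. The enrichment of the
    negative (nonregulated) set is 1 by construction. ``selected_genes``
    are regulated transcripts whose hit count strictly exceeds the mean
    over the regulated set; ties at the mean are excluded.
    """
    if not regulated_transcripts or not negative_transcripts:
        raise ValueError("empty transcript set")
    if length_correction not in ("mean_ratio", "per_nt"):
        raise ValueError("length_correction must be 'mean_ratio' or 'per_nt'")
    t_counts = {r.gene: len(count_motif_hits(r, rbp_motif, pvalue, background))
                for r in regulated_transcripts}
    n_counts = {r.gene: len(count_motif_hits(r, rbp_motif, pvalue, background))
                for r in negative_transcripts}
    if length_correction == "per_nt":
        t_rate = sum(t_counts.values()) / sum(len(r) for r in regulated_transcripts)
        n_rate = sum(n_counts.values()) / sum(len(r) for r in negative_transcripts)
        c = 1.0
    else:
        t_rate = sum(t_counts.values()) / len(regulated_transcripts)
        n_rate = sum(n_counts.values()) / len(negative_transcripts)
        c = length_correction_coefficient(regulated_transcripts, negative_transcripts)
    note = ""
    if t_rate == 0:
        ratio = 0.0
        note = "motif absent from the regulated set"
    elif n_rate == 0:
        ratio = math.inf
        note = "motif absent from the negative set; ratio unbounded"
    else:
        ratio = t_rate / (n_rate * c)
    mean_count = np.mean(list(t_counts.values()))
    selected = sorted(g for g, k in t_counts.items() if k > mean_count)
    return CofactorEnrichment(
        rbp=rbp_motif.name, motif=rbp_motif.iupac or "pwm",
        target_rate=float(t_rate), negative_rate=float(n_rate),
        length_coefficient=float(c), enrichment_ratio=float(ratio),
        selected_genes=selected, note=note,
    )


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

@dataclass
class TermEnrichmentResult:
    """Hypergeometric over-representation of one term in a gene subset."""

    term: str
    k: int        # subset genes annotated to the term
    n_subset: int
    K: int        # background genes annotated to the term
    N: int        # background size
    p: float      # hypergeometric upper tail P(X >= k)
    p_bonf: float
    passes: bool


def term_enrichment(
    subset: set[str],
    background: set[str],
    gene2term: Mapping[str, Iterable[str]],
    min_genes: int = 3,
    min_pct: float = 0.04,
    alpha: float = 0.05,
) -> list[TermEnrichmentResult]:
    """Hypergeometric term enrichment with Bonferroni and count/percentage filters.

    ``gene2term`` maps term -> genes (a flat annotation; no hierarchy
    traversal). Only terms with at least ``min_genes`` background genes are
    tested, and Bonferroni is over those tested terms. A term passes iff
    k >= min_genes, k / |subset| >= min_pct and Bonferroni-adjusted
    p <= alpha.
    """
    subset = set(subset) & set(background)
    if not subset:
        raise ValueError("subset is empty (after restricting to the background)")
    N = len(background)
    n = len(subset)
    tested = {term: set(genes) & background for term, genes in gene2term.items()}
    tested = {t: g for t, g in tested.items() if len(g) >= min_genes}
    m = len(tested)
    results = []
    for term in sorted(tested):
        in_term = tested[term]
        K = len(in_term)
        k = len(in_term & subset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_bonf = min(1.0, p * m)
        passes = k >= min_genes and (k / n) >= min_pct and p_bonf <= alpha
        results.append(TermEnrichmentResult(term=term, k=k, n_subset=n, K=K, N=N,
                                            p=p, p_bonf=p_bonf, passes=passes))
    return results


# ---------------------------------------------------------------------------
# Regulon graph
# ---------------------------------------------------------------------------

def build_regulon(
    interactors: Iterable[InteractorCall],
    enrichments: Mapping[tuple[str, str], CofactorEnrichment],
    term_results: Mapping[tuple[str, str], Sequence[TermEnrichmentResult]],
    ratio_threshold: float = 2.0,
) -> nx.MultiDiGraph:
    """Assemble the layered PUM -> RBP cofactor -> mRNA-group regulon graph.

    Interaction edges come from the MS interactor calls (one edge per RNase
    condition in which the interaction was observed). A coregulation edge
    RBP -> term is added when the RBP is an interactor of the PUM (a
    cofactor is an interactor by definition), the (PUM, RBP) motif
    enrichment ratio exceeds ``ratio_threshold``, and the term passes its
    filters; the edge carries the enrichment ratio and the term's
    Bonferroni p.
    """
    g = nx.MultiDiGraph()
    for call in interactors:
        g.add_node(call.protein, kind="rbp")
        pums = ("PUM1", "PUM2") if call.bait == "both" else (call.bait,)
        kinds = {
            "dependent": ("interaction_rna_dependent",),
            "independent": ("interaction_rna_independent",),
            "both": ("interaction_rna_dependent", "interaction_rna_independent"),
        }[call.rna_dependence]
        for pum in pums:
            g.add_node(pum, kind="pum")
            for kind in kinds:
                g.add_edge(pum, call.protein, kind=kind)
    for (pum, rbp), enr in enrichments.items():
        if not (enr.enrichment_ratio > ratio_threshold):
            continue
        if rbp not in g or not g.has_edge(pum, rbp):
            continue
        for tr in term_results.get((pum, rbp), []):
            if not tr.passes:
                continue
            if tr.term not in g:
                g.add_node(tr.term, kind="term")
            g.add_edge(rbp, tr.term, kind="coregulation", pum=pum,
                       enrichment_ratio=float(enr.enrichment_ratio), term_p=float(tr.p_bonf))
    return g


def interactors_to_frame(calls: Iterable[InteractorCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def enrichments_to_frame(enrichments: Mapping[tuple[str, str], CofactorEnrichment]) -> pd.DataFrame:
    rows = []
    for (pum, rbp), e in enrichments.items():
        rows.append({"pum": pum, "rbp": rbp, "motif": e.motif,
                     "target_rate": e.target_rate, "negative_rate": e.negative_rate,
                     "length_coefficient": e.length_coefficient,
                     "enrichment_ratio": e.enrichment_ratio,
                     "n_selected_genes": len(e.selected_genes), "note": e.note})
    return pd.DataFrame(rows)
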