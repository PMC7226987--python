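"""Motif scanning and enrichment primitives for RBP regulatory elements.

This module implements the sequence-level machinery of the pipeline:

* IUPAC degenerate-word expansion and exact-word scanning (the PUM-binding
  element, PBE, ``UGUAHAUW`` is the motivating case: H = A/C/U, W = A/U);
* PWM log-odds scanning with an exact p-value -> score-threshold conversion
  computed by dynamic programming over the discretized background score
  distribution (FIMO-style semantics);
* regional attribution of hits to 5'UTR / CDS / 3'UTR;
* per-set summary statistics (mean hits per sequence, fraction of sequences
  with at least one hit, regional percentages);
* the Altschul-Erickson dinucleotide-preserving shuffle;
* exhaustive discriminative word discovery (sequence-level presence,
  one-sided Fisher test, BH correction) as a transparent stand-in for
  heuristic discovery tools.

All sequences are handled in the RNA alphabet; ``T`` is accepted on input
and canonicalized to ``U``. Coordinates are 0-based, half-open. Scanning is
on the mRNA sense strand only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC degenerate nucleotide codes, RNA alphabet (T is an alias of U).
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: The classic PUM-binding element, as a degenerate word.
PBE_IUPAC = "UGUAHAUW"


def canonical_rna(seq: str) -> str:
    """Upper-case ``seq`` and map T->U. Raises on non-nucleotide letters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide letters in sequence: {sorted(bad)}")
    return s


def expand_iupac(motif: str) -> set[str]:
    """Expand a degenerate IUPAC word into the set of concrete RNA words.

    ``expand_iupac("UGUAHAUW")`` yields the 6 classic PBE words (3 x 2
    combinations of H and W).
    """
    if not motif:
        raise ValueError("empty IUPAC motif")
    try:
        choices = [IUPAC_CODES[c] for c in motif.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in {motif!r}") from None
    return {"".join(w) for w in itertools.product(*choices)}


@dataclass(frozen=True)
class MotifHit:
    """A single motif match on one transcript.

    ``start`` is 0-based on the mature mRNA; ``region`` (if attributed) is
    one of ``utr5`` / ``cds`` / ``utr3``, decided by the region containing
    the hit's start position. ``score`` is the PWM log-odds (None for exact
    IUPAC matches).
    """

    gene: str
    start: int
    width: int
    region: str | None = None
    score: float | None = None
    motif: str = ""


def scan_iupac(
    seq: str,
    motif: str,
    count_overlaps: bool = True,
    gene: str = "",
    motif_name: str = "",
) -> list[MotifHit]:
    """Find all matches of a degenerate IUPAC word in ``seq``.

    Overlapping matches are counted by default (FIMO behaviour). With
    ``count_overlaps=False``, scanning resumes after the end of each match.
    """
    s = canonical_rna(seq)
    try:
        allowed = [IUPAC_CODES[c] for c in motif.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in {motif!r}") from None
    w = len(allowed)
    name = motif_name or motif
    if w == 0:
        raise ValueError("empty motif")
    if len(s) < w:
        return []
    # vectorized positional membership: AND of shifted per-position masks
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    n_windows = len(s) - w + 1
    match = np.ones(n_windows, dtype=bool)
    for j, letters in enumerate(allowed):
        col = arr[j : j + n_windows]
        ok = np.zeros(n_windows, dtype=bool)
        for b in letters:
            ok |= col == ord(b)
        match &= ok
    starts = np.flatnonzero(match)
    if not count_overlaps:
        kept = []
        nxt = 0
        for i in starts:
            if i >= nxt:
                kept.append(i)
                nxt = i + w
        starts = kept
    return [MotifHit(gene=gene, start=int(i), width=w, motif=name) for i in starts]


# ---------------------------------------------------------------------------
# PWM scanning with exact p-value -> threshold conversion
# ---------------------------------------------------------------------------

def pwm_from_iupac(motif: str, pseudocount: float = 1e-4) -> np.ndarray:
    """Build a width x 4 probability matrix (columns A,C,G,U) from an IUPAC word.

    Allowed bases share probability uniformly; disallowed bases receive
    ``pseudocount`` before row renormalization.
    """
    rows = []
    for c in motif.upper():
        allowed = IUPAC_CODES.get(c)
        if allowed is None:
            raise ValueError(f"invalid IUPAC letter {c!r}")
        row = np.full(4, pseudocount)
        for b in allowed:
            row[_BASE_INDEX[b]] = 1.0 / len(allowed)
        rows.append(row / row.sum())
    return np.asarray(rows)


class PwmScorer:
    """Log-odds scorer for a PWM with integer score discretization.

    Scores are ``log2(p_ij / background_i)`` rounded to multiples of
    ``granularity``. The same integer representation is used by the
    threshold DP and by scanning, so a threshold derived from a p-value is
    applied exactly, and for small widths the DP reproduces the exhaustive
    enumeration over all 4^w words.
    """

    def __init__(
        self,
        pwm: np.ndarray,
        background: Sequence[float] | None = None,
        granularity: float = 1e-3,
        pseudocount: float = 1e-4,
    ):
        pwm = np.asarray(pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError("PWM must be width x 4 (columns A,C,G,U)")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if (pwm <= 0).any():
            # degenerate columns: pseudocount before log-odds
            pwm = pwm + pseudocount
            pwm = pwm / pwm.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6) or (bg <= 0).any():
            raise ValueError("background must be 4 positive frequencies summing to 1")
        self.background = bg
        self.granularity = float(granularity)
        self.logodds = np.log2(pwm / bg)
        self.int_scores = np.rint(self.logodds / self.granularity).astype(np.int64)
        self.width = pwm.shape[0]

    def score_int(self, word: str) -> int:
        idx = [_BASE_INDEX[b] for b in canonical_rna(word)]
        if len(idx) != self.width:
            raise ValueError("word length does not match PWM width")
        return int(sum(self.int_scores[j, i] for j, i in enumerate(idx)))

    def score(self, word: str) -> float:
        return self.score_int(word) * self.granularity

    def score_distribution(self) -> dict[int, float]:
        """Background distribution of the integer score, by column-wise DP."""
        dist: dict[int, float] = {0: 1.0}
        for j in range(self.width):
            nxt: dict[int, float] = {}
            col = self.int_scores[j]
            for s, p in dist.items():
                for i in range(4):
                    key = s + int(col[i])
                    nxt[key] = nxt.get(key, 0.0) + p * self.background[i]
            dist = nxt
        return dist

    def threshold_int_from_pvalue(self, p: float) -> int:
        """Smallest achievable integer score t with P_bg(score >= t) <= p.

        If no achievable score satisfies the bound (p below the point mass
        of the best word under the background), the maximum achievable score
        is returned, so the consensus word(s) still pass.
        """
        if not 0 < p <= 1:
            raise ValueError("p must be in (0, 1]")
        dist = self.score_distribution()
        scores = sorted(dist, reverse=True)
        tail = 0.0
        best: int | None = None
        for s in scores:
            tail += dist[s]
            if tail <= p + 1e-15:
                best = s
            else:
                break
        return best if best is not None else scores[0]

    def threshold_from_pvalue(self, p: float) -> float:
        return self.threshold_int_from_pvalue(p) * self.granularity

    def scan(self, seq: str, threshold: float, gene: str = "", motif_name: str = "") -> list[MotifHit]:
        """All windows with integer score >= the discretized threshold."""
        s = canonical_rna(seq)
        if threshold == float("inf") or len(s) < self.width:
            return []
        t_int = int(round(threshold / self.granularity))
        idx = np.fromiter((_BASE_INDEX.get(c, -1) for c in s), dtype=np.int64, count=len(s))
        n_windows = len(s) - self.width + 1
        total = np.zeros(n_windows, dtype=np.int64)
        valid = np.ones(n_windows, dtype=bool)
        for j in range(self.width):
            col = idx[j : j + n_windows]
            valid &= col >= 0  # windows containing N never match
            total += self.int_scores[j][np.clip(col, 0, 3)]
        starts = np.flatnonzero(valid & (total >= t_int))
        return [
            MotifHit(gene=gene, start=int(i), width=self.width,
                     score=float(total[i] * self.granularity), motif=motif_name)
            for i in starts
        ]


def pwm_threshold_from_pvalue(
    pwm: np.ndarray,
    background: Sequence[float] | None = None,
    p: float = 0.01,
    granularity: float = 1e-3,
) -> float:
    """Score threshold t with P_background(score >= t) <= p (see PwmScorer)."""
    return PwmScorer(pwm, background, granularity).threshold_from_pvalue(p)


def scan_pwm(
    seq: str,
    pwm: np.ndarray,
    threshold: float,
    background: Sequence[float] | None = None,
    granularity: float = 1e-3,
    gene: str = "",
    motif_name: str = "",
) -> list[MotifHit]:
    """Scan ``seq`` with a PWM at a fixed log-odds threshold."""
    return PwmScorer(pwm, background, granularity).scan(seq, threshold, gene, motif_name)


# ---------------------------------------------------------------------------
# Regional attribution and per-set statistics
# ---------------------------------------------------------------------------

REGIONS = ("utr5", "cds", "utr3")


def attribute_regions(hits: Iterable[MotifHit], record) -> list[MotifHit]:
    """Return hits with ``region`` set from the transcript's annotation.

    A hit spanning a region boundary is attributed to the region containing
    its start position.
    """
    out = []
    for h in hits:
        out.append(MotifHit(gene=h.gene or record.gene, start=h.start, width=h.width,
                            region=record.region_of(h.start), score=h.score, motif=h.motif))
    return out


def region_distribution(hits: Iterable[MotifHit],
                        annotations: Mapping[str, object] | None = None) -> tuple[float, float, float]:
    """Percentages of hits per region (utr5, cds, utr3); sums to 100.

    Hits lacking a region are attributed via ``annotations`` (gene ->
    TranscriptRecord). Raises if there are no hits.
    """
    counts = dict.fromkeys(REGIONS, 0)
    n = 0
    for h in hits:
        region = h.region
        if region is None:
            if annotations is None or h.gene not in annotations:
                raise ValueError(f"hit on {h.gene!r} has no region and no annotation given")
            region = annotations[h.gene].region_of(h.start)
        counts[region] += 1
        n += 1
    if n == 0:
        raise ValueError("no hits: region distribution undefined")
    return tuple(100.0 * counts[r] / n for r in REGIONS)


@dataclass
class MotifSetStats:
    """Per-set motif content summary over a collection of transcripts."""

    n_sequences: int
    mean_hits_per_sequence: float
    frac_with_at_least_one: float
    region_pct: tuple[float, float, float] | None
    per_gene_counts: dict[str, int] = field(default_factory=dict, repr=False)


def count_motif_hits(record, motif, pvalue: float = 0.01,
                     background: Sequence[float] | None = None,
                     count_overlaps: bool = True) -> list[MotifHit]:
    """Scan one transcript with an IUPAC word or a MotifDefinition.

    PWM motifs are scanned at the score threshold matching ``pvalue`` under
    ``background``; IUPAC motifs use exact degenerate-word matching.
    """
    if isinstance(motif, str):
        hits = scan_iupac(record.sequence, motif, count_overlaps, gene=record.gene)
    elif getattr(motif, "kind", None) == "iupac":
        hits = scan_iupac(record.sequence, motif.iupac, count_overlaps,
                          gene=record.gene, motif_name=motif.name)
    elif getattr(motif, "kind", None) == "pwm":
        scorer = PwmScorer(motif.pwm, background)
        t = scorer.threshold_from_pvalue(pvalue)
        hits = scorer.scan(record.sequence, t, gene=record.gene, motif_name=motif.name)
    else:
        raise TypeError(f"unsupported motif object: {motif!r}")
    return attribute_regions(hits, record)


def motif_set_stats(
    transcripts: Sequence,
    motif,
    top_n: int | None = None,
    ranking: Mapping[str, float] | None = None,
    pvalue: float = 0.01,
    background: Sequence[float] | None = None,
    count_overlaps: bool = True,
) -> MotifSetStats:
    """Motif content of a transcript set: mean hits/sequence, fraction with >= 1 hit.

    With ``top_n`` and ``ranking`` (gene -> enrichment fold), the statistics
    are restricted to the ``top_n`` highest-ranked genes, mirroring "top
    targets" analyses.
    """
    records = list(transcripts)
    if not records:
        raise ValueError("empty transcript set")
    if top_n is not None:
        if ranking is None:
            raise ValueError("top_n requires a ranking")
        records = sorted(records, key=lambda r: ranking.get(r.gene, float("-inf")),
                         reverse=True)[:top_n]
    counts: dict[str, int] = {}
    all_hits: list[MotifHit] = []
    for rec in records:
        hits = count_motif_hits(rec, motif, pvalue, background, count_overlaps)
        counts[rec.gene] = len(hits)
        all_hits.extend(hits)
    n = len(records)
    total = sum(counts.values())
    region_pct = region_distribution(all_hits) if all_hits else None
    return MotifSetStats(
        n_sequences=n,
        mean_hits_per_sequence=total / n,
        frac_with_at_least_one=sum(1 for c in counts.values() if c > 0) / n,
        region_pct=region_pct,
        per_gene_counts=counts,
    )


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide multiset.

    Altschul-Erickson method: build the multigraph of adjacent-letter
    transitions, fix a random spanning "last-edge" arborescence into the
    final letter so an Eulerian walk exists, shuffle the remaining edge
    lists, and read the walk off. Deterministic for a given seed.
    """
    s = canonical_rna(seq)
    if len(s) <= 2:
        return s
    rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(10_000):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        # every vertex must reach `last` by following chosen last-edges
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for valid input
        raise RuntimeError("failed to sample an Eulerian last-edge tree")
    lists: dict[str, list[str]] = {}
    for v, out in edges.items():
        rest = list(out)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        lists[v] = rest
    walk = [s[0]]
    cur = s[0]
    pos = dict.fromkeys(lists, 0)
    for _ in range(len(s) - 1):
        nxt = lists[cur][pos[cur]]
        pos[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


# ---------------------------------------------------------------------------
# Discriminative word discovery
# ---------------------------------------------------------------------------

def discover_words(pos_seqs: Sequence[str], neg_seqs: Sequence[str], width: int = 8) -> pd.DataFrame:
    """Exhaustively rank fixed-width words enriched in positives vs negatives.

    Presence is counted at the sequence level (a word either occurs in a
    sequence or not); enrichment is a one-sided Fisher exact test, BH
    corrected across all tested words. A transparent, exhaustive stand-in
    for heuristic discriminative-motif discovery.
    """
    pos = [canonical_rna(x) for x in pos_seqs]
    neg = [canonical_rna(x) for x in neg_seqs]
    if not pos or not neg:
        raise ValueError("need non-empty positive and negative sequence sets")
    if min(len(x) for x in pos + neg) < width:
        raise ValueError(f"width {width} exceeds the shortest sequence")

    def present(seqs: list[str]) -> dict[str, int]:
        tab: dict[str, int] = {}
        for x in seqs:
            words = {x[i : i + width] for i in range(len(x) - width + 1)}
            for w in words:
                if "N" not in w:
                    tab[w] = tab.get(w, 0) + 1
        return tab

    pos_tab = present(pos)
    neg_tab = present(neg)
    rows = []
    for w, k in pos_tab.items():
        m = neg_tab.get(w, 0)
        _, p = stats.fisher_exact(
            [[k, len(pos) - k], [m, len(neg) - m]], alternative="greater"
        )
        rows.append((w, k, len(pos), m, len(neg), p))
    df = pd.DataFrame(rows, columns=["word", "pos_with", "pos_total", "neg_with", "neg_total", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df.sort_values(["q", "p", "word"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Classic vs degenerate PBE classification
# ---------------------------------------------------------------------------

def classic_pbe_words() -> set[str]:
    """The concrete words of the classic PBE (UGUAHAUW)."""
    return expand_iupac(PBE_IUPAC)


def degenerate_pbe_words() -> set[str]:
    """8-mers with a UGUA core one substitution away from a classic PBE.

    Defined as words beginning with UGUA whose positions 5-8 are at Hamming
    distance exactly 1 from positions 5-8 of some classic word — the relaxed
    element reported for validated targets lacking a classic PBE.
    """
    classic = classic_pbe_words()
    out: set[str] = set()
    for w in classic:
        tail = w[4:]
        for j in range(4):
            for b in BASES:
                if b != tail[j]:
                    cand = "UGUA" + tail[:j] + b + tail[j + 1 :]
                    if cand not in classic:
                        out.add(cand)
    return out


def has_classic_pbe(seq: str) -> bool:
    return bool(scan_iupac(seq, PBE_IUPAC))


def has_degenerate_pbe(seq: str) -> bool:
    s = canonical_rna(seq)
    words = degenerate_pbe_words()
    return any(s[i : i + 8] in words for i in range(len(s) - 7))
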