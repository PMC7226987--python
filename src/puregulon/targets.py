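"""RIP enrichment calling, knockdown regulation classification, and set algebra.

The selection logic for "bound" mRNAs follows the three-criterion rule used
in RIP-seq studies with an IgG control and a transcriptome reference:

1. enrichment in every replicate (per-replicate fold change, pairing
   replicates by index),
2. at least ``min_fc``-fold enrichment in the IP versus IgG, and
3. at least ``min_fc``-fold enrichment versus the transcriptome,

with significance (BH-adjusted p < alpha) from a two-sample test on
log2-transformed normalized abundance. Knockdown classification calls a
gene repressed when its level rises by at least ``threshold`` (default 20%)
upon knockdown of its regulator, and activated when it falls by at least
the same margin (ratio <= 0.8), both at BH-adjusted p < alpha.

All thresholds are inclusive (>= 2-fold, >= 20%, >= 6-fold); boundary
comparisons allow a 1e-9 absolute tolerance so that ratios equal to a
printed threshold remain inclusive under floating-point rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stats import two_sample_test

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5

#: tolerance making threshold boundaries inclusive under float rounding
BOUNDARY_TOL = 1e-9


@dataclass
class EnrichmentRecord:
    """Per-gene RIP enrichment statistics and the bound call."""

    gene: str
    fc_vs_igg: tuple[float, ...]
    fc_vs_transcriptome: tuple[float, ...]
    log2fc_igg: float
    log2fc_transcriptome: float
    p: float
    q: float
    bound: bool


@dataclass
class RegulationCall:
    """Per-gene knockdown outcome: repressed / activated / unchanged."""

    gene: str
    direction: str
    effect: float  # linear ratio knockdown/control
    p: float
    q: float


class VennPartition(NamedTuple):
    """Two-set partition bookkeeping (|A|-only, |B|-only, common)."""

    a_only: int
    b_only: int
    common: int

    @property
    def size_a(self) -> int:
        return self.a_only + self.common

    @property
    def size_b(self) -> int:
        return self.b_only + self.common

    @property
    def union(self) -> int:
        return self.a_only + self.b_only + self.common

    @property
    def pct_common_of_union(self) -> float:
        return 100.0 * self.common / self.union if self.union else 0.0

    @property
    def pct_common_of_a(self) -> float:
        return 100.0 * self.common / self.size_a if self.size_a else 0.0

    @property
    def pct_common_of_b(self) -> float:
        return 100.0 * self.common / self.size_b if self.size_b else 0.0


def normalize_libraries(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to counts-per-million."""
    sums = table.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"library with zero total counts: {zero.index[0]!r}")
    return table * (1e6 / sums)


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])


def _check_tables(*tables: pd.DataFrame) -> tuple[pd.Index, int]:
    first = tables[0]
    nrep = first.shape[1]
    for t in tables[1:]:
        if not t.index.equals(first.index):
            raise ValueError("tables must share the same gene index")
        if t.shape[1] != nrep:
            raise ValueError("tables must have matched replicate counts")
    if nrep < 2:
        raise ValueError("at least 2 replicates are required (variance undefined)")
    return first.index, nrep


def _drop_all_zero(genes: pd.Index, *tables: pd.DataFrame):
    total = sum(t.sum(axis=1) for t in tables)
    dead = total[total == 0].index
    if len(dead):
        logger.info("dropping %d genes with zero counts in every sample", len(dead))
    keep = genes.difference(dead, sort=False)
    return keep, [t.loc[keep] for t in tables]


def rip_enrichment(
    ip_table: pd.DataFrame,
    igg_table: pd.DataFrame,
    transcriptome_table: pd.DataFrame,
    min_fc: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = PSEUDOCOUNT,
    test: str = "moderated",
) -> list[EnrichmentRecord]:
    """Call bound mRNAs from normalized IP, IgG and transcriptome tables.

    Per-replicate fold changes pair replicates by column order. The per-gene
    p-value is the larger of the two two-sample tests (IP vs IgG, IP vs
    transcriptome) on log2(abundance + pseudocount) — enrichment must be
    supported against both references — with BH correction across genes.
    ``test`` selects the gene-wise test ('moderated' variance-shrinkage t,
    'student', or 'welch'; see :mod:`puregulon.stats`). Genes with zero
    counts everywhere are dropped with a log record.
    """
    genes, _ = _check_tables(ip_table, igg_table, transcriptome_table)
    genes, (ip, igg, txm) = _drop_all_zero(genes, ip_table, igg_table, transcriptome_table)

    ipv = ip.to_numpy() + pseudocount
    iggv = igg.to_numpy() + pseudocount
    txmv = txm.to_numpy() + pseudocount
    fc_igg = ipv / iggv
    fc_txm = ipv / txmv
    log_ip, log_igg, log_txm = (np.log2(x) for x in (ipv, iggv, txmv))
    p1 = two_sample_test(log_ip, log_igg, method=test)
    p2 = two_sample_test(log_ip, log_txm, method=test)
    p = np.fmax(p1, p2)
    q = _bh(p)
    pooled_igg = np.log2(ipv.mean(axis=1)) - np.log2(iggv.mean(axis=1))
    pooled_txm = np.log2(ipv.mean(axis=1)) - np.log2(txmv.mean(axis=1))

    records = []
    for i, g in enumerate(genes):
        enriched = bool((fc_igg[i] >= min_fc - BOUNDARY_TOL).all()
                        and (fc_txm[i] >= min_fc - BOUNDARY_TOL).all())
        records.append(
            EnrichmentRecord(
                gene=g,
                fc_vs_igg=tuple(fc_igg[i]),
                fc_vs_transcriptome=tuple(fc_txm[i]),
                log2fc_igg=float(pooled_igg[i]),
                log2fc_transcriptome=float(pooled_txm[i]),
                p=float(p[i]),
                q=float(q[i]),
                bound=enriched and q[i] < alpha,
            )
        )
    return records


def classify_kd(
    kd_table: pd.DataFrame,
    ctrl_table: pd.DataFrame,
    threshold: float = 0.20,
    alpha: float = 0.05,
    pseudocount: float = PSEUDOCOUNT,
    test: str = "moderated",
) -> list[RegulationCall]:
    """Classify each gene's response to knockdown versus control.

    effect = mean(kd) / mean(control) on normalized abundance (+pseudocount).
    Repressed: effect >= 1 + threshold and q < alpha (the mRNA rises when
    its repressor is depleted). Activated: effect <= 1 - threshold and
    q < alpha. Otherwise unchanged.
    """
    genes, _ = _check_tables(kd_table, ctrl_table)
    genes, (kd, ctrl) = _drop_all_zero(genes, kd_table, ctrl_table)
    kdv = kd.to_numpy() + pseudocount
    ctv = ctrl.to_numpy() + pseudocount
    effect = kdv.mean(axis=1) / ctv.mean(axis=1)
    p = two_sample_test(np.log2(kdv), np.log2(ctv), method=test)
    q = _bh(p)
    calls = []
    for i, g in enumerate(genes):
        if effect[i] >= 1.0 + threshold - BOUNDARY_TOL and q[i] < alpha:
            direction = "repressed"
        elif effect[i] <= 1.0 - threshold + BOUNDARY_TOL and q[i] < alpha:
            direction = "activated"
        else:
            direction = "unchanged"
        calls.append(RegulationCall(gene=g, direction=direction,
                                    effect=float(effect[i]), p=float(p[i]), q=float(q[i])))
    return calls


def intersect_regulated(bound: set[str], calls: Iterable[RegulationCall]) -> dict[str, str]:
    """Regulated targets: bound genes with a significant knockdown response.

    Returns gene -> 'repressed' | 'activated'.
    """
    return {c.gene: c.direction for c in calls
            if c.direction != "unchanged" and c.gene in bound}


def venn_partition(a: set[str] | int, b: set[str] | int, common: int | None = None) -> VennPartition:
    """Partition two gene sets (or reconstruct a partition from printed counts).

    ``venn_partition(A, B)`` with sets computes the partition; with integers
    ``venn_partition(a_only, b_only, common)`` it wraps printed counts for
    bookkeeping checks.
    """
    if isinstance(a, int):
        if not isinstance(b, int) or common is None:
            raise TypeError("integer form requires (a_only, b_only, common)")
        if min(a, b, common) < 0:
            raise ValueError("partition counts must be non-negative")
        return VennPartition(a, b, common)
    inter = len(a & b)
    return VennPartition(len(a) - inter, len(b) - inter, inter)


class KsShift(NamedTuple):
    """Two-sample Kolmogorov-Smirnov comparison of log2 fold changes."""

    statistic: float
    pvalue: float
    direction: str  # 'up' | 'down' | 'none' (median shift of targets vs control)


def ks_shift(target_log2fc: Sequence[float], control_log2fc: Sequence[float]) -> KsShift:
    """Two-sided two-sample KS test for a cumulative distribution shift.

    The D statistic is the supremum of the ECDF difference, computed
    directly; the p-value comes from scipy's two-sided two-sample test.
    """
    x = np.sort(np.asarray(target_log2fc, float))
    y = np.sort(np.asarray(control_log2fc, float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / len(x)
    fy = np.searchsorted(y, grid, side="right") / len(y)
    d = float(np.max(np.abs(fx - fy)))
    pvalue = float(stats.ks_2samp(x, y, alternative="two-sided").pvalue)
    mx, my = np.median(x), np.median(y)
    direction = "up" if mx > my else ("down" if mx < my else "none")
    return KsShift(statistic=d, pvalue=pvalue, direction=direction)


def select_germline_enriched(
    cell_table: pd.DataFrame | pd.Series,
    somatic_table: pd.DataFrame | pd.Series,
    fold: float = 6.0,
    pseudocount: float = PSEUDOCOUNT,
) -> set[str]:
    """Genes whose cell-line expression is >= ``fold`` times the somatic level.

    Means are taken across replicates when tables are given; a pseudocount
    keeps the ratio finite when the somatic level is zero. The fold
    threshold is inclusive.
    """
    cell = cell_table.mean(axis=1) if isinstance(cell_table, pd.DataFrame) else cell_table
    somatic = somatic_table.mean(axis=1) if isinstance(somatic_table, pd.DataFrame) else somatic_table
    if not cell.index.equals(somatic.index):
        raise ValueError("cell and somatic tables must share the same gene index")
    ratio = (cell + pseudocount) / (somatic + pseudocount)
    return set(ratio.index[ratio >= fold - BOUNDARY_TOL])


def records_to_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "gene": r.gene,
            **{f"fc_igg_rep{i + 1}": v for i, v in enumerate(r.fc_vs_igg)},
            **{f"fc_txm_rep{i + 1}": v for i, v in enumerate(r.fc_vs_transcriptome)},
            "log2fc_igg": r.log2fc_igg, "log2fc_transcriptome": r.log2fc_transcriptome,
            "p": r.p, "q": r.q, "bound": r.bound,
        })
    return pd.DataFrame(rows)


def calls_to_frame(calls: Iterable[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
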