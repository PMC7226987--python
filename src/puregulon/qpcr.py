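"""RT-qPCR relative quantification (delta-delta-Ct) and significance calls.

Quantification normalizes each target Ct to the arithmetic mean of the
reference-gene Cts (equivalent to geometric-mean normalization of the
linear quantities), then to a calibrator condition:

    dCt   = Ct_target - mean(Ct_references)          (per replicate)
    ddCt  = dCt_condition - mean(dCt_calibrator)
    fold  = 2^-ddCt

The point estimate is the geometric mean of the replicate folds, i.e.
2^-(mean ddCt), so a condition measured against itself is exactly 1.
Significance uses a Shapiro-Wilk normality check per group followed by an
unpaired two-sided t-test (Welch by default), with the conventional star
code: * p < 0.05, ** p < 0.005, *** p < 0.0005, **** p < 0.00005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCES = ("ACTB", "GAPDH")

STAR_THRESHOLDS = ((0.00005, "****"), (0.0005, "***"), (0.005, "**"), (0.05, "*"))


class CtTable:
    """Gene x condition x replicate Ct values with designated reference genes.

    Wraps a long-format frame (columns gene, condition, replicate, ct).
    All Ct values must be positive; every condition needs at least
    ``min_replicates`` replicates; the reference genes must be measured in
    every condition.
    """

    def __init__(self, data: pd.DataFrame,
                 reference_genes: Sequence[str] = DEFAULT_REFERENCES,
                 min_replicates: int = 3):
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"Ct table lacks columns {sorted(missing)}")
        df = data[["gene", "condition", "replicate", "ct"]].copy()
        if (df["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if df.duplicated(["gene", "condition", "replicate"]).any():
            raise ValueError("duplicate (gene, condition, replicate) measurement")
        for cond, grp in df.groupby("condition"):
            nrep = grp["replicate"].nunique()
            if nrep < min_replicates:
                raise ValueError(f"condition {cond!r} has {nrep} replicates (< {min_replicates})")
        genes = set(df["gene"])
        for ref in reference_genes:
            if ref not in genes:
                raise ValueError(f"reference gene {ref!r} missing from the table")
            for cond in df["condition"].unique():
                if df[(df["gene"] == ref) & (df["condition"] == cond)].empty:
                    raise ValueError(f"reference gene {ref!r} missing in condition {cond!r}")
        self.data = df
        self.reference_genes = tuple(reference_genes)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - set(self.reference_genes))

    def _ct(self, gene: str, condition: str) -> pd.Series:
        sub = self.data[(self.data["gene"] == gene) & (self.data["condition"] == condition)]
        if sub.empty:
            raise KeyError(f"no Ct values for gene {gene!r} in condition {condition!r}")
        return sub.set_index("replicate")["ct"].sort_index()

    def delta_ct(self, gene: str, condition: str) -> pd.Series:
        """Per-replicate Ct normalized to the mean of the reference genes."""
        target = self._ct(gene, condition)
        refs = pd.concat([self._ct(r, condition) for r in self.reference_genes], axis=1)
        if refs.isna().any().any():
            raise ValueError(f"reference replicates incomplete in condition {condition!r}")
        return target - refs.mean(axis=1)


@dataclass
class RelativeExpression:
    """ddCt fold change of one gene in one condition versus a calibrator."""

    gene: str
    condition: str
    calibrator: str
    replicate_folds: tuple[float, ...]
    fold: float  # geometric mean of the replicate folds


def relative_expression(ct: CtTable, target: str, condition: str,
                        calibrator_condition: str) -> RelativeExpression:
    """ddCt fold change (linear) of ``target`` versus the calibrator condition."""
    dct = ct.delta_ct(target, condition)
    dct_cal = ct.delta_ct(target, calibrator_condition)
    ddct = dct - dct_cal.mean()
    folds = tuple(float(f) for f in 2.0 ** (-ddct))
    return RelativeExpression(
        gene=target, condition=condition, calibrator=calibrator_condition,
        replicate_folds=folds, fold=float(2.0 ** (-ddct.mean())),
    )


def stars(p: float) -> str:
    """Significance star code (strict thresholds, most significant first)."""
    for cutoff, mark in STAR_THRESHOLDS:
        if p < cutoff:
            return mark
    return ""


@dataclass
class SignificanceResult:
    shapiro_p: tuple[float, float]
    t_p: float
    stars: str
    normality_warning: bool = field(default=False)


def significance(group_a: Sequence[float], group_b: Sequence[float],
                 equal_var: bool = False, alpha_normality: float = 0.05) -> SignificanceResult:
    """Shapiro-Wilk per group, then an unpaired two-sided t-test with stars.

    A normality warning is flagged (not an error) when either group fails
    Shapiro-Wilk at ``alpha_normality``. ``equal_var=True`` selects the
    classic pooled-variance test instead of Welch.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    sw_a = float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else 1.0
    sw_b = float(stats.shapiro(b).pvalue) if np.ptp(b) > 0 else 1.0
    if np.ptp(np.concatenate([a, b])) == 0:
        t_p = 1.0  # identical constant groups: no evidence of a difference
    else:
        t_p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        if np.isnan(t_p):
            t_p = 1.0
    return SignificanceResult(
        shapiro_p=(sw_a, sw_b), t_p=t_p, stars=stars(t_p),
        normality_warning=(sw_a < alpha_normality or sw_b < alpha_normality),
    )
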