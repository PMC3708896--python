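"""Parental-bias statistics over the DEG union.

For each DEG the normalized divergence from each parent is the absolute
RPKM difference relative to the hybrid level; the bias statistic is their
difference:

    d = |C - A| / C  -  |C - B| / C

A positive ``d`` means the gene's expression in the hybrid diverged more
from the paternal parent (A) than from the maternal parent (B); a
negative value means the converse.  Summing over DEGs, an excess of
positive values indicates directional expression change away from the
paternal parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEFAULT_EPSILON
from .errors import ConfigError
from .quantify import round_half_up

#: |d| below this counts as exactly zero (floating-point "final value of zero").
ZERO_TOL = 1e-12


def bias_statistic(
    rpkm_a, rpkm_b, rpkm_c, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray | float:
    """Per-gene d = |C-A|/C - |C-B|/C on RPKM values.

    Hybrid zeros are floored at ``epsilon`` so the statistic stays
    finite; genes at zero in all three libraries carry no signal and
    should be excluded upstream.
    """
    a = np.asarray(rpkm_a, dtype=float)
    b = np.asarray(rpkm_b, dtype=float)
    c = np.maximum(np.asarray(rpkm_c, dtype=float), epsilon)
    d = np.abs(c - a) / c - np.abs(c - b) / c
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class BiasSummary:
    """Sign counts of d over the scored DEGs, with rounded shares."""

    n_scored: int
    positive: int
    negative: int
    zero: int
    percent_positive: float
    percent_negative: float
    percent_zero: float
    binomial_p: float  # two-sided sign test of positive vs negative

    def to_dict(self) -> dict:
        return {
            "n_scored": self.n_scored,
            "positive": self.positive,
            "negative": self.negative,
            "zero": self.zero,
            "percent_positive": self.percent_positive,
            "percent_negative": self.percent_negative,
            "percent_zero": self.percent_zero,
            "binomial_p": self.binomial_p,
        }


def bias_summary(d_values) -> BiasSummary:
    """Exact sign counts of the bias statistic and a sign test.

    Percentages are rounded half-up to the nearest percent; the binomial
    p-value tests positive-vs-negative balance (zeros excluded).
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise ConfigError("no bias values to summarize")
    zero = int((np.abs(d) < ZERO_TOL).sum())
    pos = int((d >= ZERO_TOL).sum())
    neg = int((d <= -ZERO_TOL).sum())
    n = d.size
    if pos + neg > 0:
        p = float(stats.binomtest(pos, pos + neg, 0.5).pvalue)
    else:
        p = 1.0
    return BiasSummary(
        n_scored=n,
        positive=pos,
        negative=neg,
        zero=zero,
        percent_positive=float(round_half_up(pos / n * 100.0)),
        percent_negative=float(round_half_up(neg / n * 100.0)),
        percent_zero=float(round_half_up(zero / n * 100.0)),
        binomial_p=p,
    )


def score_deg_union(
    expression: pd.DataFrame,
    deg_ca: pd.DataFrame,
    deg_cb: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.Series:
    """Bias statistic for every gene that is a DEG in either comparison.

    Genes with zero RPKM in all three libraries are dropped (logged by
    count in the returned series' attrs).
    """
    deg_union = deg_ca.index[deg_ca["is_deg"]].union(deg_cb.index[deg_cb["is_deg"]])
    expr = expression.loc[deg_union]
    allzero = (expr[["A", "B", "C"]] == 0).all(axis=1)
    expr = expr[~allzero]
    d = bias_statistic(expr["A"], expr["B"], expr["C"], epsilon=epsilon)
    out = pd.Series(d, index=expr.index, name="bias_d")
    out.attrs["excluded_all_zero"] = int(allzero.sum())
    return out


def summed_fold_change(deg_table: pd.DataFrame, method: str = "fold_change") -> float:
    """Total expression divergence of one comparison's DEGs.

    ``method="fold_change"`` sums the max/min RPKM ratios (each >= 1);
    ``method="abs_log2fc"`` sums |log2 fold changes| instead.  Either way
    the total grows with both the number and the strength of DEGs.
    """
    deg = deg_table[deg_table["is_deg"]]
    if len(deg) == 0:
        return 0.0
    if method == "fold_change":
        return float(deg["fold_change"].sum())
    if method == "abs_log2fc":
        return float(np.abs(deg["log2fc"]).sum())
    raise ConfigError(f"unknown summed fold-change method {method!r}")
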