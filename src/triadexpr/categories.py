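"""Functional-category contrasts between additive and nonadditive genes.

Given an additivity classification and a user-supplied gene-to-category
annotation (one row per gene/category pair; genes may carry several
categories), each category is tested with Fisher's exact test on the
2x2 table

                 in category   not in category
    nonadditive      a               b
    additive         c               d

with Benjamini-Hochberg adjustment across categories.  The enrichment
direction compares the category's proportion among nonadditive genes
with its proportion among additive genes (odds ratio vs 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ConfigError

logger = logging.getLogger(__name__)


def contrast_categories(
    calls: pd.DataFrame, categories: pd.DataFrame
) -> pd.DataFrame:
    """Fisher-test every category for additive/nonadditive imbalance.

    Parameters
    ----------
    calls
        Additivity classification indexed by gene id with a ``label``
        column (``additive`` / ``nonadditive``).
    categories
        Frame with ``gene_id`` and ``category`` columns.  Genes absent
        from ``calls`` are ignored; categories with no member in either
        class are skipped with a log notice.

    Returns
    -------
    Frame indexed by category with member counts, odds ratio, p, fdr and
    ``direction`` (more_nonadditive / more_additive / balanced).
    """
    for col in ("gene_id", "category"):
        if col not in categories.columns:
            raise ConfigError(f"annotation table lacks a {col!r} column")
    labels = calls["label"]
    n_nonadd = int((labels == "nonadditive").sum())
    n_add = int((labels == "additive").sum())
    if n_nonadd == 0 or n_add == 0:
        raise ConfigError("both additive and nonadditive genes are required")

    ann = categories[categories["gene_id"].isin(labels.index)]
    rows = []
    for cat, sub in ann.groupby("category", sort=True):
        members = labels.loc[labels.index.intersection(pd.Index(sub["gene_id"]))]
        a = int((members == "nonadditive").sum())
        c = int((members == "additive").sum())
        if a == 0 and c == 0:
            logger.info("category %r has no classified members; skipped", cat)
            continue
        b = n_nonadd - a
        d = n_add - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "category": cat,
                "nonadditive_in": a,
                "nonadditive_out": b,
                "additive_in": c,
                "additive_out": d,
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "p_value": float(p),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "nonadditive_in",
                "nonadditive_out",
                "additive_in",
                "additive_out",
                "odds_ratio",
                "p_value",
                "fdr",
                "direction",
            ]
        )
    out = pd.DataFrame(rows).set_index("category")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["direction"] = np.select(
        [out["odds_ratio"] > 1, out["odds_ratio"] < 1],
        ["more_nonadditive", "more_additive"],
        default="balanced",
    )
    return out
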