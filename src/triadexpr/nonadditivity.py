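"""Midparent-value construction and additive/nonadditive classification.

Under purely additive inheritance the hybrid's expression of a gene is
the average of its parents' levels - the midparent value (MPV), defined
here on RPKM: MPV = (RPKM_A + RPKM_B) / 2.  Because the exact count test
needs a count/total pair rather than an expression level, the MPV is
back-projected onto a pseudo-library whose total is the rounded mean of
the parental totals and whose per-gene pseudo-count reproduces the MPV
RPKM to rounding:

    pseudo_total = round((N_A + N_B) / 2)
    pseudo_count = round(MPV_RPKM * length_kb * pseudo_total / 1e6)

The hybrid library is then tested against this pseudo-library exactly as
against a real one; genes with fold change >= 2 and FDR <= 0.001 versus
the MPV are nonadditive, all others additive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import (
    DEFAULT_EPSILON,
    DEFAULT_FC_MIN,
    DEFAULT_FDR_MAX,
    ac_test,
    bh_adjust,
    fold_change,
)
from .errors import ConfigError
from .quantify import CountMatrix, _length_series, round_half_up


def _round_half_up_int(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def midparent(
    counts: CountMatrix, expression: pd.DataFrame, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Build the midparent pseudo-library.

    Returns a frame (indexed like the count matrix) with ``mpv_rpkm`` and
    ``pseudo_count`` columns, plus the pseudo-library total.
    """
    lengths = _length_series(catalog).loc[counts.gene_ids].astype(float)
    mpv_rpkm = (expression["A"].to_numpy() + expression["B"].to_numpy()) / 2.0
    pseudo_total = int(
        _round_half_up_int(
            np.array((float(counts.totals["A"]) + float(counts.totals["B"])) / 2.0)
        )
    )
    kb = lengths.to_numpy() / 1000.0
    pseudo_count = _round_half_up_int(mpv_rpkm * kb * pseudo_total / 1e6)
    frame = pd.DataFrame(
        {"mpv_rpkm": mpv_rpkm, "pseudo_count": pseudo_count},
        index=counts.gene_ids,
    )
    return frame, pseudo_total


def classify_additivity(
    counts: CountMatrix,
    expression: pd.DataFrame,
    catalog: pd.DataFrame,
    fc_min: float = DEFAULT_FC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    epsilon: float = DEFAULT_EPSILON,
    min_count: int = 1,
) -> pd.DataFrame:
    """Label every testable gene additive or nonadditive versus the MPV.

    The tested universe is every gene expressed in the hybrid
    (count >= ``min_count``) or with an MPV pseudo-count >= 1; BH runs
    over that universe.  ``deviation_direction`` is "above"/"below" the
    midparent for nonadditive genes and "none" for additive ones.
    """
    if fc_min < 1:
        raise ConfigError("fc_min must be >= 1")
    if not 0 < fdr_max <= 1:
        raise ConfigError("fdr_max must lie in (0, 1]")
    mpv, pseudo_total = midparent(counts, expression, catalog)
    hybrid = counts.counts["C"].to_numpy()
    pseudo = mpv["pseudo_count"].to_numpy()
    universe = (hybrid >= min_count) | (pseudo >= 1)
    idx = counts.gene_ids[universe]

    x = pseudo[universe]
    y = hybrid[universe]
    n_c = float(counts.totals["C"])
    p = np.atleast_1d(ac_test(x, y, float(pseudo_total), n_c))
    fdr = bh_adjust(p)

    r_c = expression["C"].to_numpy(dtype=float)[universe]
    r_mpv = mpv["mpv_rpkm"].to_numpy(dtype=float)[universe]
    fc = fold_change(r_mpv, r_c, epsilon)
    log2dev = np.log2(np.maximum(r_c, epsilon) / np.maximum(r_mpv, epsilon))
    nonadd = (fc >= fc_min) & (fdr <= fdr_max)
    direction = np.where(nonadd, np.where(log2dev > 0, "above", "below"), "none")

    out = pd.DataFrame(
        {
            "mpv_rpkm": r_mpv,
            "mpv_pseudocount": x,
            "hybrid_count": y,
            "hybrid_rpkm": r_c,
            "fold_change": fc,
            "log2_dev": log2dev,
            "p_value": p,
            "fdr": fdr,
            "label": np.where(nonadd, "nonadditive", "additive"),
            "deviation_direction": direction,
        },
        index=pd.Index(idx, name="gene_id"),
    )
    out.attrs["pseudo_total"] = pseudo_total
    out.attrs["comparison"] = "C-vs-MPV"
    return out


def nonadditive_percent(n_nonadditive: int, n_detected: int) -> float:
    """Nonadditive genes as a percent of all detected genes, 3 decimals."""
    if n_detected <= 0:
        raise ConfigError("n_detected must be positive")
    return float(round_half_up(n_nonadditive / n_detected * 100.0, 3))


def additivity_summary(calls: pd.DataFrame, n_detected: int) -> dict:
    """Headline counts for an additivity classification."""
    n_nonadd = int((calls["label"] == "nonadditive").sum())
    return {
        "tested": int(len(calls)),
        "nonadditive": n_nonadd,
        "additive": int(len(calls)) - n_nonadd,
        "above_mpv": int((calls["deviation_direction"] == "above").sum()),
        "below_mpv": int((calls["deviation_direction"] == "below").sum()),
        "detected_genes": int(n_detected),
        "nonadditive_percent": nonadditive_percent(n_nonadd, n_detected),
    }


def deg_overlap(
    calls: pd.DataFrame,
    deg_ca: pd.DataFrame,
    deg_cb: pd.DataFrame,
    patterns: pd.DataFrame | None = None,
) -> dict:
    """Cross-tabulate nonadditive genes with the two DEG sets.

    Reports how many nonadditive genes are DEGs in either hybrid/parent
    comparison and, when a pattern assignment is given, how the
    differentially expressed nonadditive genes split over the four
    expression groups.
    """
    nonadd = set(calls.index[calls["label"] == "nonadditive"])
    deg_a = set(deg_ca.index[deg_ca["is_deg"]])
    deg_b = set(deg_cb.index[deg_cb["is_deg"]])
    union = deg_a | deg_b
    overlap = nonadd & union
    out = {
        "nonadditive": len(nonadd),
        "nonadditive_and_deg": len(overlap),
        "nonadditive_deg_vs_A": len(nonadd & deg_a),
        "nonadditive_deg_vs_B": len(nonadd & deg_b),
        "nonadditive_not_deg": len(nonadd - union),
    }
    if patterns is not None:
        groups = patterns.loc[patterns.index.isin(overlap), "group"]
        for g in (1, 2, 3, 4):
            out[f"group_{g}"] = int((groups == g).sum())
    return out
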