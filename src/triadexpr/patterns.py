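"""Expression-pattern grouping of DEGs and hierarchical clustering.

Each gene's profile is the pair of binary-log ratios of the hybrid over
its parents, (log2(C/A), log2(C/B)).  The four canonical patterns are the
sign quadrants of that profile:

    group 1: down vs A, down vs B   (suppressed in the hybrid)
    group 2: down vs A, up  vs B
    group 3: up  vs A, down vs B
    group 4: up  vs A, up  vs B    (highest in the hybrid)

A gene receives a *cluster* label when it is a DEG in both comparisons
and a *group* label when it is a DEG in at least one; when both apply the
labels coincide.  A log ratio of exactly 0 counts as "down" so the four
patterns always partition.  An agglomerative clustering (average linkage,
Pearson-correlation distance) over the two-dimensional profiles is
provided as a concordance check; note that correlation distance between
length-2 vectors is inherently coarse (it reduces to the sign of the
centered slope), which the sign rule does not suffer from.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .diffexpr import DEFAULT_EPSILON
from .errors import ConfigError

logger = logging.getLogger(__name__)


def log_ratio_profiles(
    expression: pd.DataFrame, epsilon: float = DEFAULT_EPSILON
) -> pd.DataFrame:
    """Per-gene (log2(C/A), log2(C/B)) profiles with zeros floored."""
    if epsilon <= 0:
        raise ConfigError("epsilon must be positive")
    a = np.maximum(expression["A"].to_numpy(dtype=float), epsilon)
    b = np.maximum(expression["B"].to_numpy(dtype=float), epsilon)
    c = np.maximum(expression["C"].to_numpy(dtype=float), epsilon)
    return pd.DataFrame(
        {"log2_CA": np.log2(c / a), "log2_CB": np.log2(c / b)},
        index=expression.index,
    )


def sign_group(l2a, l2b) -> np.ndarray:
    """Quadrant group of a profile; ratio <= 0 counts as down."""
    up_a = np.asarray(l2a) > 0
    up_b = np.asarray(l2b) > 0
    return np.where(up_a, np.where(up_b, 4, 3), np.where(up_b, 2, 1)).astype(np.int8)


def assign_patterns(
    deg_ca: pd.DataFrame, deg_cb: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Assign cluster (both-significant) and group (either-significant).

    Returns a frame over the union of the two tested universes with
    columns log2_CA, log2_CB, sig_vs_A, sig_vs_B, cluster, group; 0 in
    ``cluster``/``group`` means no assignment.
    """
    idx = deg_ca.index.union(deg_cb.index)
    missing = idx.difference(profiles.index)
    if len(missing) > 0:
        raise ConfigError(
            f"{len(missing)} gene(s) lack log-ratio profiles: {list(missing[:5])}"
        )
    sig_a = deg_ca["is_deg"].reindex(idx, fill_value=False).to_numpy(dtype=bool)
    sig_b = deg_cb["is_deg"].reindex(idx, fill_value=False).to_numpy(dtype=bool)
    l2a = profiles["log2_CA"].loc[idx].to_numpy()
    l2b = profiles["log2_CB"].loc[idx].to_numpy()
    quad = sign_group(l2a, l2b)
    group = np.where(sig_a | sig_b, quad, 0).astype(np.int8)
    cluster = np.where(sig_a & sig_b, quad, 0).astype(np.int8)
    return pd.DataFrame(
        {
            "log2_CA": l2a,
            "log2_CB": l2b,
            "sig_vs_A": sig_a,
            "sig_vs_B": sig_b,
            "cluster": cluster,
            "group": group,
        },
        index=idx,
    )


def group_counts(assignment: pd.DataFrame, column: str = "group") -> dict[int, int]:
    """Number of genes per pattern (1-4), excluding unassigned genes."""
    return {g: int((assignment[column] == g).sum()) for g in (1, 2, 3, 4)}


def hierarchical_cluster(
    profiles: pd.DataFrame, k: int = 4
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of log-ratio profiles.

    Average linkage on 1 - Pearson correlation between profile vectors,
    cut to ``k`` flat clusters.  Profiles with zero variance (both ratios
    equal) have no defined correlation; they are withheld from the tree
    and attached afterwards to the nearest cluster mean in Euclidean
    distance, with a log notice.  Deterministic for a fixed input order
    (scipy's linkage breaks ties by the lowest pair index).

    Returns (labels indexed like ``profiles``, linkage matrix over the
    non-degenerate profiles).
    """
    x = profiles.to_numpy(dtype=float)
    n = len(x)
    if n < k:
        raise ConfigError(f"need at least k={k} profiles, got {n}")
    degenerate = x.std(axis=1) == 0
    core = x[~degenerate]
    if len(core) < 2:
        raise ConfigError("too few non-constant profiles to cluster")
    dist = pdist(core, metric="correlation")
    # guard the metric's floating-point noise around exact 0 distance
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(dist, method="average")
    core_labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = np.zeros(n, dtype=int)
    labels[~degenerate] = core_labels
    if degenerate.any():
        logger.warning(
            "%d constant profile(s) assigned by Euclidean fallback",
            int(degenerate.sum()),
        )
        centroids = np.vstack(
            [core[core_labels == c].mean(axis=0) for c in np.unique(core_labels)]
        )
        cids = np.unique(core_labels)
        for i in np.where(degenerate)[0]:
            d = np.linalg.norm(centroids - x[i], axis=1)
            labels[i] = cids[int(np.argmin(d))]
    return pd.Series(labels, index=profiles.index, name="hcluster"), linkage


def linkage_to_newick(linkage: np.ndarray, leaf_names) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)
    names = list(leaf_names)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
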