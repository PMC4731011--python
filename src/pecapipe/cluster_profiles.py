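"""Hierarchical clustering of combined RNA/protein profiles.

Profiles (concatenated RNA and protein time series over both replicates)
are clustered with correlation distance (1 - Pearson r between rows) and
average linkage.  Two cutting modes are provided: a *static* cut of the
dendrogram at a fixed height (reference mode, default 0.604) and a
*dynamic* cut that adapts to the tree shape by recursive branch splitting
under a minimum cluster size, in the spirit of the dynamic tree-cut
algorithm (deep splitting off).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ConfigurationError, ExpressionMatrix

STATIC = "static"
DYNAMIC = "dynamic"


def combine_profiles(
    rna: list[ExpressionMatrix], protein: list[ExpressionMatrix]
) -> pd.DataFrame:
    """Concatenate RNA and protein series (all replicates) row-wise per gene."""
    blocks = []
    genes: pd.Index | None = None
    for m in rna + protein:
        genes = m.gene_ids if genes is None else genes.intersection(m.gene_ids)
    for m in rna + protein:
        b = m.values.loc[genes].copy()
        b.columns = [f"{m.level}_r{m.replicate}_{t:g}" for t in m.time_grid]
        blocks.append(b)
    return pd.concat(blocks, axis=1)


def _linkage(profiles: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if profiles.shape[0] < 2:
        raise ConfigurationError("clustering needs >= 2 genes")
    centered = profiles.sub(profiles.mean(axis=1), axis=0)
    dist = pdist(centered.to_numpy(dtype=float), metric="correlation")
    return hierarchy.linkage(dist, method="average"), dist


def cluster_profiles(
    profiles: pd.DataFrame,
    method: str = STATIC,
    cut: float = 0.604,
    min_size: int = 30,
) -> pd.DataFrame:
    """Cluster gene profiles; returns gene_id-indexed assignment table.

    Columns: ``cluster`` (1-based, relabelled by decreasing size; in
    dynamic mode 0 marks genes shed as unassigned), ``order`` (dendrogram
    leaf position) and ``method``.  Static mode cuts the average-linkage
    dendrogram at the given correlation-distance height; dynamic mode
    descends the dendrogram recursively under a minimum branch size, so
    clusters follow the tree shape at varying heights instead of one
    global cut.
    """
    if method not in (STATIC, DYNAMIC):
        raise ConfigurationError(f"unknown clustering method {method!r}")
    Z, _ = _linkage(profiles)
    leaves = hierarchy.leaves_list(Z)
    if method == STATIC:
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    else:
        labels = _dynamic_cut(Z, min_size, profiles.shape[0], cut)
    # relabel clusters by decreasing size for stable downstream selection
    # (label 0 = unassigned in dynamic mode and is preserved)
    assigned = labels[labels > 0] if (labels == 0).any() else labels
    sizes = pd.Series(assigned).value_counts()
    relabel = {old: new + 1 for new, old in enumerate(sizes.index)}
    relabel[0] = 0
    out = pd.DataFrame(
        {
            "cluster": [relabel[v] for v in labels],
            "order": np.argsort(leaves).astype(int),
            "method": method,
        },
        index=profiles.index,
    )
    out.index.name = "gene_id"
    return out


def _dynamic_cut(Z: np.ndarray, min_size: int, n: int, core_height: float) -> np.ndarray:
    """Recursive tree cut with a minimum branch size and grey shedding.

    Descent starts at the root.  A branch whose top merge lies at or below
    ``core_height`` is a coherent core and becomes one cluster (it is never
    shredded further).  Above that height, a merge of two viable branches
    (each >= ``min_size`` leaves) splits — so clusters are detected at
    whatever height they join, not at one global cut — while a merge with
    an undersized branch sheds that runt as unassigned (label 0, the
    "grey" group) and continues down the main branch; this carries the cut
    past the long chains that loosely-correlated genes form.  A branch
    above ``core_height`` with no viable children at all has no tight core
    and goes entirely grey."""
    root = hierarchy.to_tree(Z)
    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def assign(node):
        for leaf in node.pre_order(lambda x: x.id):
            labels[leaf] = next_label[0]
        next_label[0] += 1

    def descend(node):
        if node.dist <= core_height:
            assign(node)
            return
        left, right = node.get_left(), node.get_right()
        big_l, big_r = left.get_count() >= min_size, right.get_count() >= min_size
        if big_l and big_r:
            descend(left)
            descend(right)
        elif big_l or big_r:
            # runt child stays unassigned; follow the main branch down
            descend(left if big_l else right)
        # else: loose branch with no viable core -> grey

    if root.get_count() >= min_size:
        descend(root)
    elif n:
        assign(root)
    return labels


def cluster_rate_ratio_means(
    assignment: pd.DataFrame,
    profiles: dict[str, pd.DataFrame],
    top_k: int = 6,
) -> pd.DataFrame:
    """Mean log rate ratio per interval for the K largest clusters.

    ``profiles`` maps level -> genes x intervals posterior-mean rate
    ratios.  Returns a table indexed by (cluster, level).
    """
    assigned = assignment[assignment["cluster"] > 0]
    sizes = assigned["cluster"].value_counts()
    top = list(sizes.index[:top_k])
    rows = {}
    for cluster in top:
        members = assignment.index[assignment["cluster"] == cluster]
        for level, theta in profiles.items():
            shared = members.intersection(theta.index)
            if shared.empty:
                continue
            rows[(cluster, level)] = theta.loc[shared].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.names = ["cluster", "level"]
    return out


def export_heatmap_matrix(
    combined: pd.DataFrame,
    assignment: pd.DataFrame,
    to_log10: bool = False,
) -> pd.DataFrame:
    """Median-centered matrix ordered by cluster and dendrogram position.

    ``to_log10`` converts natural-log values to base-10 log before
    centering (concentration heatmaps are drawn in log10 units).
    """
    df = combined.copy()
    if to_log10:
        df = df / np.log(10.0)
    df = df.sub(df.median(axis=1), axis=0)
    key = assignment.loc[df.index]
    order = key.sort_values(["cluster", "order"]).index
    return df.loc[order]
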