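"""Community distance matrices: Bray-Curtis and tree-aware UniFrac family.

Generalized UniFrac (Chen et al. form) weights each branch by the relative
abundances of its descendants in the two samples:

    d(u, v) = sum_i b_i (p_i + q_i)^alpha |p_i - q_i| / (p_i + q_i)
              ---------------------------------------------------
              sum_i b_i (p_i + q_i)^alpha

with branch lengths ``b_i`` and descendant proportions ``p_i``/``q_i``;
branches absent from both samples are skipped.  ``alpha=1`` reduces to
weighted-normalized UniFrac and ``alpha=0`` down-weights abundant lineages.
Unweighted UniFrac uses the same traversal with presence/absence in place
of proportions.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from ._table import FeatureTable

__all__ = ["bray_curtis", "generalized_unifrac", "unweighted_unifrac"]


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on counts:
    ``d(u,v) = 1 - 2 sum(min(u_i, v_i)) / (sum(u) + sum(v))``."""
    if len(table.counts) < 2:
        raise ValueError("need >= 2 samples")
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        raise ValueError(f"zero-sum samples: {list(sums.index[sums == 0])}")
    mat = squareform(pdist(table.counts.to_numpy(float), metric="braycurtis"))
    return DistanceMatrix(mat, ids=table.sample_ids)


def _as_tree(tree: TreeNode | str) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(io.StringIO(tree))


def _branch_proportions(table: FeatureTable, tree: TreeNode | str):
    """Branch lengths and per-sample descendant-proportion matrix.

    Returns ``(lengths, P)`` where ``P[s, i]`` is the fraction of sample
    ``s``'s reads whose genus descends through branch ``i`` (the root's
    unlengthed stem is excluded).
    """
    t = _as_tree(tree)
    tip_names = {tip.name for tip in t.tips()}
    missing = sorted(set(table.genera) - tip_names)
    if missing:
        raise ValueError(f"genera absent from the tree: {missing}")
    rel = table.relative_abundance()
    n = len(rel)
    col_of = {g: j for j, g in enumerate(rel.columns)}

    lengths: list[float] = []
    profiles: list[np.ndarray] = []
    # postorder accumulation of descendant proportions per node
    node_prop: dict[int, np.ndarray] = {}
    for node in t.postorder(include_self=True):
        if node.is_tip():
            prop = (
                rel.iloc[:, col_of[node.name]].to_numpy(float)
                if node.name in col_of
                else np.zeros(n)
            )
        else:
            prop = np.zeros(n)
            for child in node.children:
                prop = prop + node_prop[id(child)]
        node_prop[id(node)] = prop
        if node.parent is not None and node.length is not None:
            lengths.append(float(node.length))
            profiles.append(prop)
    return np.asarray(lengths), np.column_stack(profiles)


def generalized_unifrac(
    table: FeatureTable, tree: TreeNode | str, alpha: float = 0.5
) -> DistanceMatrix:
    """Generalized UniFrac distance matrix over all sample pairs.

    ``alpha`` in [0, 1] controls the weight put on abundant lineages
    (default 0.5, the method's canonical recommendation; 1 equals
    weighted-normalized UniFrac).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    lengths, P = _branch_proportions(table, tree)
    n = P.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        p = P[i]
        q = P[i + 1 :]
        tot = p + q                      # (m, branches)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(tot > 0, np.abs(p - q) / np.where(tot > 0, tot, 1.0), 0.0)
            weight = lengths * np.where(tot > 0, tot**alpha, 0.0)
        denom = weight.sum(axis=1)
        num = (weight * ratio).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(denom > 0, num / denom, 0.0)
        mat[i, i + 1 :] = d
        mat[i + 1 :, i] = d
    return DistanceMatrix(mat, ids=table.sample_ids)


def unweighted_unifrac(table: FeatureTable, tree: TreeNode | str) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length over total branch length,
    with branch presence judged from the descendant proportions."""
    lengths, P = _branch_proportions(table, tree)
    pres = (P > 0).astype(float)
    n = pres.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        a = pres[i]
        b = pres[i + 1 :]
        union = np.maximum(a, b)
        sym = np.abs(a - b)
        denom = (lengths * union).sum(axis=1)
        num = (lengths * sym).sum(axis=1)
        d = np.where(denom > 0, num / denom, 0.0)
        mat[i, i + 1 :] = d
        mat[i + 1 :, i] = d
    return DistanceMatrix(mat, ids=table.sample_ids)
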