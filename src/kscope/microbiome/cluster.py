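"""Enterotype-style clustering on distance matrices.

Communities are partitioned with PAM (partitioning around medoids: greedy
BUILD initialization followed by best-improvement SWAP), the cluster number
is chosen by a four-way consensus — Calinski-Harabasz on a principal
coordinate embedding, mean silhouette width, the within-cluster
sum-of-distances elbow, and Tibshirani-Walther prediction strength — and
nested structure is sought divide-and-compare style: each top-level cluster
is re-clustered on its restricted distance matrix and split only when the
consensus supports k >= 2 and the split's silhouette clears a floor.
Samples that sit badly in their cluster (negative silhouette) at any level
are set aside as unclassified rather than forced into a subcluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from sklearn.metrics import (
    calinski_harabasz_score,
    silhouette_samples,
    silhouette_score,
)

__all__ = [
    "ClusterSolution",
    "OptimalKResult",
    "DivComResult",
    "pam_cluster",
    "optimal_k",
    "prediction_strength",
    "divcom_subcluster",
]


@dataclass
class ClusterSolution:
    """A flat partition of samples around medoids."""

    assignment: pd.Series            # sample id -> cluster index (0-based)
    medoids: list[str]               # medoid sample ids, one per cluster
    k: int
    objective: float                 # sum of within-cluster distances to medoids
    quality: dict[str, float] = field(default_factory=dict)
    unclassified: set[str] = field(default_factory=set)

    def labels(self) -> np.ndarray:
        return self.assignment.to_numpy()


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: start from the 1-medoid minimizer, then repeatedly add
    the point that most reduces the total distance to nearest medoid.
    Ties break to the lowest index."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
        nearest = np.minimum(nearest, d[:, medoids[-1]])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    """Best-improvement SWAP until no medoid/non-medoid exchange lowers the
    objective.  The objective is non-increasing across iterations."""
    medoids = list(medoids)
    n = d.shape[0]
    for _ in range(max_iter):
        cost = d[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in med_set:
                    continue
                new_cost = np.minimum(base, d[:, h]).sum()
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    return medoids


def pam_cluster(dist: DistanceMatrix, k: int) -> ClusterSolution:
    """Partitioning around medoids with BUILD + SWAP.

    Deterministic for a given distance matrix: all ties break to the lowest
    sample index, and each sample joins its nearest medoid (first medoid on
    ties, so duplicate points co-assign).
    """
    n = dist.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    d = dist.data
    medoids = _pam_swap(d, _pam_build(d, k))
    order = np.argsort(medoids, kind="stable")
    medoids = [medoids[i] for i in order]
    assign = np.argmin(d[:, medoids], axis=1)
    objective = float(d[np.arange(n), [medoids[a] for a in assign]].sum())
    ids = list(dist.ids)
    return ClusterSolution(
        assignment=pd.Series(assign, index=ids),
        medoids=[ids[m] for m in medoids],
        k=k,
        objective=objective,
    )


def _wss(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def _pcoa_embedding(dist: DistanceMatrix, max_axes: int = 10) -> np.ndarray:
    """First min(max_axes, n-1) principal coordinates of the distance
    matrix, used only to feed coordinate-based indices (CH)."""
    dims = min(max_axes, dist.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ord_res = pcoa(dist, method="eigh", dimensions=dims)
    return ord_res.samples.to_numpy()


def prediction_strength(
    dist: DistanceMatrix, k: int, n_halvings: int = 10, seed: int | None = None
) -> float:
    """Tibshirani-Walther prediction strength of a k-clustering.

    For each random halving, both halves are PAM-clustered; test-half
    samples are then classified by their nearest training-half medoid, and
    for every test cluster we score the fraction of its co-member pairs
    that the training medoids also co-assign.  The halving's score is the
    minimum over test clusters; PS(k) is the mean over halvings.
    """
    rng = np.random.default_rng(seed)
    d = dist.data
    n = d.shape[0]
    if n < 2 * (k + 1):
        raise ValueError("too few samples for a prediction-strength halving")
    scores = []
    for _ in range(n_halvings):
        perm = rng.permutation(n)
        half = n // 2
        train, test = np.sort(perm[:half]), np.sort(perm[half:])
        med_train = _pam_swap(d[np.ix_(train, train)], _pam_build(d[np.ix_(train, train)], k))
        med_train = train[med_train]
        sub_test = d[np.ix_(test, test)]
        med_test = _pam_swap(sub_test, _pam_build(sub_test, k))
        test_assign = np.argmin(sub_test[:, med_test], axis=1)
        train_assign = np.argmin(d[np.ix_(test, med_train)], axis=1)
        worst = 1.0
        for c in range(k):
            members = np.flatnonzero(test_assign == c)
            m = len(members)
            if m < 2:
                continue
            co = train_assign[members][:, None] == train_assign[members][None, :]
            agree = (co.sum() - m) / (m * (m - 1))
            worst = min(worst, agree)
        scores.append(worst)
    return float(np.mean(scores))


@dataclass
class OptimalKResult:
    consensus_k: int
    votes: dict[str, int]
    index_table: pd.DataFrame        # per-k CH, silhouette, WSS, PS
    solutions: dict[int, ClusterSolution]


def optimal_k(
    dist: DistanceMatrix,
    k_range: range | None = None,
    seed: int | None = None,
    ps_threshold: float = 0.8,
    n_halvings: int = 10,
) -> OptimalKResult:
    """Consensus cluster number from four indices.

    Votes: CH (argmax over the PCoA embedding), mean silhouette (argmax),
    WSS elbow (argmax of the second forward difference, using the k=1
    solution as anchor), and prediction strength (largest k with
    PS >= ``ps_threshold``; a vote of 1 records "no supported split").
    Consensus is the modal vote, ties resolving to the smaller k; an
    all-indices-disagree table is returned for inspection either way.
    """
    n = dist.shape[0]
    if k_range is None:
        k_range = range(2, 11)
    ks = [k for k in k_range if k < n]
    if not ks:
        raise ValueError("empty k range")
    if n < 2 * max(ks):
        raise ValueError(f"need n >= {2 * max(ks)} samples for k_range up to {max(ks)}")
    d = dist.data
    if np.allclose(d, 0):
        raise ValueError("degenerate (all-zero) distance matrix")
    emb = _pcoa_embedding(dist)
    rng = np.random.default_rng(seed)

    rows = []
    solutions: dict[int, ClusterSolution] = {}
    wss_by_k = {1: _wss(d, [int(np.argmin(d.sum(axis=1)))])}
    for k in ks:
        sol = pam_cluster(dist, k)
        labels = sol.labels()
        ch = float(calinski_harabasz_score(emb, labels))
        sil = float(silhouette_score(d, labels, metric="precomputed"))
        ps = prediction_strength(dist, k, n_halvings=n_halvings,
                                 seed=int(rng.integers(2**31)))
        wss_by_k[k] = sol.objective
        sol.quality = {"CH": ch, "silhouette": sil, "WSS": sol.objective, "PS": ps}
        solutions[k] = sol
        rows.append({"k": k, "CH": ch, "silhouette": sil,
                     "WSS": sol.objective, "PS": ps})
    table = pd.DataFrame(rows).set_index("k")

    votes: dict[str, int] = {
        "CH": int(table["CH"].idxmax()),
        "silhouette": int(table["silhouette"].idxmax()),
    }
    # WSS elbow: largest curvature WSS(k+1) - 2 WSS(k) + WSS(k-1)
    curv = {
        k: wss_by_k[k + 1] - 2 * wss_by_k[k] + wss_by_k[k - 1]
        for k in ks
        if (k - 1 in wss_by_k) and (k + 1 in wss_by_k)
    }
    votes["WSS"] = max(curv, key=curv.get) if curv else ks[0]
    passing = [k for k in ks if table.loc[k, "PS"] >= ps_threshold]
    votes["PS"] = max(passing) if passing else 1
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    return OptimalKResult(consensus_k=int(top), votes=votes,
                          index_table=table, solutions=solutions)


@dataclass
class DivComResult:
    top: ClusterSolution
    subcluster: pd.Series            # sample id -> flat subcluster label
    hierarchy: dict[str, list[str]]  # top-cluster label -> subcluster labels
    unclassified: set[str]
    reports: dict[str, OptimalKResult | None]


def divcom_subcluster(
    dist: DistanceMatrix,
    top_solution: ClusterSolution,
    min_size: int = 4,
    seed: int | None = None,
    s_min: float = 0.25,
    k_range: range | None = None,
) -> DivComResult:
    """Divide-and-compare recursive subclustering.

    Each top-level cluster with at least ``min_size`` members is
    re-clustered on its restricted distance matrix; it splits only when the
    consensus cluster number is >= 2 *and* the split's mean silhouette is at
    least ``s_min``.  Samples with a negative silhouette at the top level or
    within their subcluster split are moved to the unclassified set.
    Returns flat labels like ``C1-sub2`` alongside the hierarchy.
    """
    if min_size < 4:
        raise ValueError("min_size must be >= 4 (two clusters of two)")
    d = dist.data
    ids = np.asarray(dist.ids)
    top_labels = top_solution.labels()
    unclassified: set[str] = set()
    if top_solution.k > 1:
        sil_top = silhouette_samples(d, top_labels, metric="precomputed")
        unclassified |= set(ids[sil_top < 0])

    rng = np.random.default_rng(seed)
    flat = pd.Series(index=top_solution.assignment.index, dtype=object)
    hierarchy: dict[str, list[str]] = {}
    reports: dict[str, OptimalKResult | None] = {}
    for c in range(top_solution.k):
        top_name = f"C{c + 1}"
        members = np.flatnonzero(top_labels == c)
        member_ids = ids[members]
        if len(members) < min_size:
            flat[member_ids] = top_name
            hierarchy[top_name] = [top_name]
            reports[top_name] = None
            continue
        sub = DistanceMatrix(d[np.ix_(members, members)], ids=list(member_ids))
        sub_range = k_range or range(2, min(10, len(members) // 2) + 1)
        res = optimal_k(sub, sub_range, seed=int(rng.integers(2**31)))
        reports[top_name] = res
        split = res.consensus_k >= 2
        if split:
            sol = res.solutions[res.consensus_k]
            if sol.quality["silhouette"] < s_min:
                split = False
        if not split:
            flat[member_ids] = top_name
            hierarchy[top_name] = [top_name]
            continue
        sub_labels = sol.labels()
        sil_sub = silhouette_samples(sub.data, sub_labels, metric="precomputed")
        unclassified |= set(member_ids[sil_sub < 0])
        names = [f"{top_name}-sub{j + 1}" for j in range(sol.k)]
        flat[member_ids] = [names[j] for j in sub_labels]
        hierarchy[top_name] = names
    subcluster = flat[~flat.index.isin(unclassified)]
    return DivComResult(
        top=top_solution,
        subcluster=subcluster,
        hierarchy=hierarchy,
        unclassified=unclassified,
        reports=reports,
    )
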