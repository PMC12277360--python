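"""Group statistics for genus tables: rank tests, PERMANOVA, core-genus
selection, discriminant effect sizes and pairwise differential heatmatrices.

The differential machinery is deliberately rank-based: genus abundances are
compositional and heavy-tailed, so comparisons use Kruskal-Wallis /
Wilcoxon rank-sum statistics, optionally on centered log-ratio (CLR)
transformed counts, with Benjamini-Hochberg correction where several
pairwise comparisons are combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from ._table import FeatureTable

__all__ = [
    "kruskal_wallis",
    "permanova",
    "CoreGenusReport",
    "core_genus_selection",
    "lda_effect_size",
    "pairwise_differential",
    "filter_pathway_table",
    "clr_transform",
]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    ``H = [12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)]``
    over g groups with rank sums ``R_j``; p from chi-square with g-1 df.
    All values tied across groups gives H=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    if correction == 0.0:          # every value identical
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return float(h), p


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_among/(a-1)) / (SS_within/(n-a)) with sums of squared
    distances; the p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    Deterministic for a given seed.  Single-member groups are allowed but
    flagged with a warning.
    """
    labels = np.asarray(pd.Series(list(labels)).astype(str))
    d2 = dist.data**2
    n = len(labels)
    if n != d2.shape[0]:
        raise ValueError("labels length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        warnings.warn("PERMANOVA group(s) with a single member", stacklevel=2)
    a = len(uniq)

    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(lab: np.ndarray) -> float:
        ss_within = 0.0
        for u in uniq:
            idx = np.flatnonzero(lab == u)
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        if ss_within <= 0:
            return np.inf
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    exceed = sum(
        pseudo_f(labels[rng.permutation(n)]) >= f_obs for _ in range(n_perm)
    )
    return float(f_obs), (1 + exceed) / (1 + n_perm)


@dataclass
class CoreGenusReport:
    """Prevalent genera, the differential core subset, and per-genus KW p."""

    prevalent: list[str]
    core: list[str]
    pvalues: pd.Series
    prevalence: pd.Series
    mode: str = "prevalence"


def core_genus_selection(
    table: FeatureTable,
    subcluster_labels: pd.Series,
    prevalence_threshold: float = 0.5,
    alpha: float = 0.05,
    mode: str = "prevalence",
    bh_adjust: bool = False,
) -> CoreGenusReport:
    """Core genera: prevalent AND differentially abundant across subclusters.

    ``mode='prevalence'`` (default) takes genera detected (count > 0) in at
    least ``prevalence_threshold`` of all samples; the alternative
    ``mode='cumulative-abundance'`` takes the smallest set of top
    mean-relative-abundance genera jointly comprising that fraction of the
    community.  The core is the subset whose relative abundance differs
    across subclusters by Kruskal-Wallis at p < ``alpha`` (raw p by
    default; ``bh_adjust`` applies Benjamini-Hochberg first).
    """
    labels = subcluster_labels.reindex(table.counts.index).dropna()
    if labels.nunique() < 2:
        raise ValueError("need >= 2 subclusters")
    rel = table.relative_abundance().loc[labels.index]
    prevalence = table.prevalence()
    if mode == "prevalence":
        prevalent = [g for g in table.genera if prevalence[g] >= prevalence_threshold]
    elif mode == "cumulative-abundance":
        means = rel.mean(axis=0).sort_values(ascending=False)
        cum = means.cumsum()
        cut = int(np.searchsorted(cum.to_numpy(), prevalence_threshold)) + 1
        prevalent = [g for g in table.genera if g in set(means.index[:cut])]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pvals = {}
    for g in prevalent:
        groups = [rel.loc[labels == lab, g].to_numpy() for lab in labels.unique()]
        _, pvals[g] = kruskal_wallis(groups)
    pvalues = pd.Series(pvals, dtype=float)
    decide = pvalues
    if bh_adjust and len(pvalues):
        decide = pd.Series(
            multipletests(pvalues.to_numpy(), method="fdr_bh")[1], index=pvalues.index
        )
    core = [g for g in prevalent if decide[g] < alpha]
    return CoreGenusReport(
        prevalent=prevalent, core=core, pvalues=pvalues,
        prevalence=prevalence, mode=mode,
    )


def lda_effect_size(
    table: FeatureTable,
    class_labels: pd.Series,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
    kw_alpha: float = 0.05,
) -> pd.DataFrame:
    """Discriminant effect sizes in the LEfSe spirit.

    Stage 1 screens features with Kruskal-Wallis across classes at
    ``kw_alpha``.  Stage 2 scores each survivor over ``n_boot`` two-thirds
    subsamples: the per-boot effect is the absolute difference between the
    enriched class's mean relative abundance and the rest (the 1-D LDA
    projection difference; for >2 classes the largest one-vs-rest gap is
    retained), and the score is the mean over boots of
    ``log10(1 + diff * 1e6)`` on the relative-abundance scale.  Features
    scoring >= ``lda_threshold`` are reported with their enriched class.
    Classes with < 3 samples are excluded with a warning.
    """
    labels = class_labels.reindex(table.counts.index).dropna().astype(str)
    sizes = labels.value_counts()
    small = sizes[sizes < 3]
    if len(small):
        warnings.warn(f"classes excluded (<3 samples): {list(small.index)}",
                      stacklevel=2)
        labels = labels[~labels.isin(small.index)]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes with >= 3 samples")
    rel = table.relative_abundance().loc[labels.index]
    rng = np.random.default_rng(seed)

    rows = []
    for feat in rel.columns:
        groups = [rel.loc[labels == c, feat].to_numpy() for c in classes]
        _, p = kruskal_wallis(groups)
        if p >= kw_alpha:
            continue
        class_means = rel.groupby(labels)[feat].mean()
        enriched = class_means.idxmax()
        effects = []
        n = len(rel)
        for _ in range(n_boot):
            idx = rng.choice(n, size=max(2, (2 * n) // 3), replace=False)
            boot_lab = labels.iloc[idx]
            if boot_lab.nunique() < 2:
                continue
            boot = rel.iloc[idx]
            diffs = []
            for c in boot_lab.unique():
                in_c = boot.loc[boot_lab == c, feat].mean()
                out_c = boot.loc[boot_lab != c, feat].mean()
                diffs.append(abs(in_c - out_c))
            effects.append(np.log10(1.0 + max(diffs) * 1e6))
        score = float(np.mean(effects)) if effects else 0.0
        rows.append({"feature": feat, "enriched_class": enriched,
                     "lda_score": score, "kw_p": p})
    out = pd.DataFrame(rows, columns=["feature", "enriched_class", "lda_score", "kw_p"])
    out = out[out["lda_score"] >= lda_threshold]
    return out.sort_values("lda_score", ascending=False).reset_index(drop=True)


def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform with a pseudocount on raw counts."""
    x = counts.to_numpy(float) + pseudocount
    logx = np.log(x)
    return pd.DataFrame(
        logx - logx.mean(axis=1, keepdims=True),
        index=counts.index, columns=counts.columns,
    )


def pairwise_differential(
    table: FeatureTable,
    strata: pd.Series,
    genera: list[str] | None = None,
    pseudocount: float = 0.5,
    mask_threshold: float = 1.0,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Signed -log10 adjusted-p matrices per genus across strata pairs.

    Counts are CLR-transformed; for every genus and every strata pair a
    two-sided Wilcoxon rank-sum test is run, Benjamini-Hochberg corrected
    across the pairs within the genus, and reported as
    ``sign(median CLR difference) * -log10(p_adj)`` — antisymmetric in the
    pair order.  The mask marks entries with magnitude > ``mask_threshold``
    (the +-1 filter).  Strata with fewer than 2 samples are excluded.
    """
    labels = strata.reindex(table.counts.index).dropna().astype(str)
    sizes = labels.value_counts()
    labels = labels[labels.isin(sizes[sizes >= 2].index)]
    strata_names = sorted(labels.unique())
    if len(strata_names) < 2:
        raise ValueError("need >= 2 strata with >= 2 samples")
    clr = clr_transform(table.counts.loc[labels.index], pseudocount)
    genera = list(genera) if genera is not None else table.genera

    matrices: dict[str, pd.DataFrame] = {}
    masks: dict[str, pd.DataFrame] = {}
    pairs = [(a, b) for i, a in enumerate(strata_names) for b in strata_names[i + 1 :]]
    for g in genera:
        raw_p, signs = [], []
        for a, b in pairs:
            va = clr.loc[labels == a, g]
            vb = clr.loc[labels == b, g]
            if va.nunique() <= 1 and vb.nunique() <= 1 and va.iloc[0] == vb.iloc[0]:
                p = 1.0
            else:
                p = float(sps.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            raw_p.append(p)
            signs.append(np.sign(va.median() - vb.median()))
        adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
        mat = pd.DataFrame(0.0, index=strata_names, columns=strata_names)
        for (a, b), p, s in zip(pairs, adj, signs):
            entry = s * -np.log10(max(p, 1e-300))
            mat.loc[a, b] = entry
            mat.loc[b, a] = -entry
        matrices[g] = mat
        masks[g] = mat.abs() > mask_threshold
    return matrices, masks


def filter_pathway_table(
    pathways: pd.DataFrame,
    mean_threshold: float = 0.005,
    zscore: bool = False,
) -> pd.DataFrame:
    """Post-filter a pathway relative-abundance table (pathways as rows).

    Duplicate pathway ids collapse to their first occurrence; rows whose
    cross-sample mean falls below ``mean_threshold`` (0.5%) are removed.
    ``zscore`` standardizes each surviving row for heatmap export
    (constant rows map to 0).
    """
    out = pathways[~pathways.index.duplicated(keep="first")]
    out = out[out.mean(axis=1) >= mean_threshold]
    if zscore:
        mean = out.mean(axis=1)
        std = out.std(axis=1, ddof=0)
        out = out.sub(mean, axis=0).div(std.replace(0.0, np.nan), axis=0).fillna(0.0)
    return out
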