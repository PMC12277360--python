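"""Synthetic skin-cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes — age-dependent declines in skin tone (ITA) and elasticity (R7), a
sebum peak in the late 20s/early 30s followed by decline, age-flat
hydration, correlated within-category measurement blocks — together with a
genus-level microbial community drawn Dirichlet-multinomial from planted
community profiles: a Streptococcus-dominant top cluster that nests two
subcommunities (one Staphylococcus/Neisseria-enriched, one
Rothia/Corynebacterium-enriched) and a Cutibacterium-dominant cluster with
no nested structure.

The default profiles plant exactly 17 genera that exceed 50% prevalence
cohort-wide; 15 of them differ strongly between subcommunities and 2 are
held homogeneous, so prevalence/Kruskal-Wallis core-genus selection has a
known answer.  All draws are deterministic given the config seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .microbiome import FeatureTable

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "default_profiles",
    "simulate_cohort",
    "simulate_responses",
    "plant_crossover",
    "write_cohort",
]

# Decade medians (ages 5, 15, ..., 85) for the latent trend paths, in the
# units of the represented metric.  Tone is ITA in degrees; elasticity is
# R7 x 100; oil is sebum in a.u. (unimodal, peaking around age 30);
# hydration has no age trend.
DEFAULT_TONE_PATH = (48.0, 46.2, 43.5, 40.6, 37.5, 35.8, 35.1, 33.1, 32.2)
DEFAULT_ELASTICITY_PATH = (67.0, 65.0, 60.2, 51.5, 47.3, 43.8, 41.2, 39.0, 38.0)
DEFAULT_OIL_PATH = (15.0, 30.0, 36.0, 37.3, 33.0, 25.0, 15.0, 9.0, 5.7)
_DECADE_MIDPOINTS = tuple(range(5, 90, 10))

# ---------------------------------------------------------------------------
# default community profiles

#: 15 planted differential core genera (enriched sets mirror the two nested
#: subcommunities), 2 planted homogeneous-but-prevalent genera, 13 rare
#: cluster-exclusive genera.
DIFFERENTIAL_GENERA = (
    "Streptococcus", "Cutibacterium", "Staphylococcus", "Neisseria",
    "Fusobacterium", "Gemella", "Prevotella", "Granulicatella",
    "Porphyromonas", "Leptotrichia", "Rothia", "Corynebacterium",
    "Actinomyces", "Lactobacillus", "Lautropia",
)
HOMOGENEOUS_GENERA = ("Haemophilus", "Veillonella")
RARE_GENERA = (
    "Micrococcus", "Moraxella", "Lawsonella", "Anaerococcus", "Finegoldia",
    "Peptoniphilus", "Dermacoccus", "Kocuria", "Brevibacterium",
    "Paracoccus", "Enhydrobacter", "Acinetobacter", "Sphingomonas",
)

# Genus weights per subcommunity.  The two DC1 subcommunities share the
# Streptococcus-dominant backbone and differ only in their secondary
# blocks, scaled so that the nested split is invisible to top-level
# clustering (prediction strength rejects k=3 cohort-wide) yet separable
# on the DC1-restricted distance matrix — the regime where only
# divide-and-compare reveals the subcommunities.
_PROFILE_SPEC: Mapping[str, Mapping[str, float]] = {
    "Staphylococcus":  {"DC1-sub1": 0.0618, "DC1-sub2": 0.0233, "DC2": 0.030},
    "Neisseria":       {"DC1-sub1": 0.0440, "DC1-sub2": 0.0160, "DC2": 0.008},
    "Fusobacterium":   {"DC1-sub1": 0.0267, "DC1-sub2": 0.0113, "DC2": 0.006},
    "Gemella":         {"DC1-sub1": 0.0225, "DC1-sub2": 0.0105, "DC2": 0.006},
    "Prevotella":      {"DC1-sub1": 0.0270, "DC1-sub2": 0.0130, "DC2": 0.008},
    "Granulicatella":  {"DC1-sub1": 0.0162, "DC1-sub2": 0.0078, "DC2": 0.005},
    "Porphyromonas":   {"DC1-sub1": 0.0162, "DC1-sub2": 0.0078, "DC2": 0.005},
    "Leptotrichia":    {"DC1-sub1": 0.0162, "DC1-sub2": 0.0078, "DC2": 0.005},
    "Rothia":          {"DC1-sub1": 0.0233, "DC1-sub2": 0.0618, "DC2": 0.020},
    "Corynebacterium": {"DC1-sub1": 0.0218, "DC1-sub2": 0.0533, "DC2": 0.035},
    "Actinomyces":     {"DC1-sub1": 0.0145, "DC1-sub2": 0.0355, "DC2": 0.008},
    "Lactobacillus":   {"DC1-sub1": 0.0113, "DC1-sub2": 0.0267, "DC2": 0.006},
    "Lautropia":       {"DC1-sub1": 0.0090, "DC1-sub2": 0.0221, "DC2": 0.005},
    "Cutibacterium":   {"DC1-sub1": 0.0600, "DC1-sub2": 0.0600, "DC2": 0.550},
    "Streptococcus":   {"DC1-sub1": 0.0000, "DC1-sub2": 0.0000, "DC2": 0.080},
    "Haemophilus":     {"DC1-sub1": 0.0200, "DC1-sub2": 0.0200, "DC2": 0.020},
    "Veillonella":     {"DC1-sub1": 0.0150, "DC1-sub2": 0.0150, "DC2": 0.015},
}
_RARE_WEIGHT = 0.004
_RARE_HOME = {  # each rare genus appears in exactly one subcommunity
    g: ("DC1-sub1", "DC1-sub2", "DC2")[i % 3] for i, g in enumerate(RARE_GENERA)
}


def default_profiles(n_genera: int = 30) -> tuple[pd.DataFrame, dict[str, str]]:
    """Default genus-probability profiles (genera x subcommunities).

    The dominant genus of each profile (Streptococcus for the two DC1
    subcommunities, Cutibacterium for DC2) absorbs the remaining
    probability mass so every column sums to exactly 1 while the planted
    homogeneous genera keep identical probabilities across profiles.
    Returns the profile table and the subcommunity -> top-cluster map.
    """
    cols = ("DC1-sub1", "DC1-sub2", "DC2")
    genera = list(DIFFERENTIAL_GENERA) + list(HOMOGENEOUS_GENERA) + list(RARE_GENERA)
    if n_genera < len(genera):
        raise ValueError(f"n_genera must be >= {len(genera)} for the default profiles")
    prof = pd.DataFrame(0.0, index=genera, columns=list(cols))
    for g, w in _PROFILE_SPEC.items():
        for c in cols:
            prof.loc[g, c] = w[c]
    for g, home in _RARE_HOME.items():
        prof.loc[g, home] = _RARE_WEIGHT
    dominant = {"DC1-sub1": "Streptococcus", "DC1-sub2": "Streptococcus",
                "DC2": "Cutibacterium"}
    for c in cols:
        prof.loc[dominant[c], c] = 0.0
        prof.loc[dominant[c], c] = 1.0 - prof[c].sum()
    for i in range(len(genera), n_genera):
        prof.loc[f"Genus{i + 1:03d}"] = 0.0
    cluster_of = {"DC1-sub1": "DC1", "DC1-sub2": "DC1", "DC2": "DC2"}
    return prof, cluster_of


@dataclass
class CohortConfig:
    """Stated world for a synthetic cohort.

    Defaults encode the conditions the analysis targets: ages 0-88, a
    female-dominated cohort, decade-median trend paths for tone/elasticity
    (declining), oil (peaking near ``oil_peak_age``) and flat hydration, a
    three-subcommunity genus profile set with DC1 nesting two
    subcommunities, Poisson sequencing depth around 5000 so rarefaction at
    1391 is exercised, and 30 genera.
    """

    n_subjects: int
    seed: int = 0
    age_range: tuple[int, int] = (0, 88)
    sex_ratio: float = 0.8                      # fraction female
    tone_decline: Sequence[float] = DEFAULT_TONE_PATH
    elasticity_decline: Sequence[float] = DEFAULT_ELASTICITY_PATH
    oil_path: Sequence[float] = DEFAULT_OIL_PATH
    oil_peak_age: int = 30
    profiles: pd.DataFrame | None = None        # genera x subcommunities
    cluster_of: Mapping[str, str] | None = None  # subcommunity -> top cluster
    subcluster_weights: Mapping[str, float] = field(
        default_factory=lambda: {"DC1-sub1": 0.34, "DC1-sub2": 0.37, "DC2": 0.29}
    )
    subcluster_split: bool = True               # False: no nested structure
    depth_mean: int = 5000
    n_genera: int = 30
    dirichlet_concentration: float = 150.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (lo, hi) with lo <= hi")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.profiles is None:
            self.profiles, derived = default_profiles(self.n_genera)
            if self.cluster_of is None:
                self.cluster_of = derived
        else:
            if self.n_genera < len(self.profiles):
                raise ValueError(
                    f"n_genera={self.n_genera} < {len(self.profiles)} genera named in profiles"
                )
            if self.cluster_of is None:
                self.cluster_of = {c: c for c in self.profiles.columns}
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"profile columns must sum to 1 (got {dict(sums)})")
        w = pd.Series(dict(self.subcluster_weights)).reindex(self.profiles.columns)
        if w.isna().any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("subcluster_weights must cover the profiles and sum to 1")


@dataclass
class SyntheticCohort:
    """A generated cohort: subjects, counts, tree, and planted truth."""

    subjects: pd.DataFrame            # indexed by subject_id; age, sex, raw columns
    counts: FeatureTable
    tree: str                         # Newick over the genus labels
    truth: dict
    config: CohortConfig

    def __post_init__(self) -> None:
        if list(self.counts.counts.index) != list(self.subjects.index):
            raise ValueError("counts row labels must equal subject identifiers")


def _interp_path(ages: np.ndarray, path: Sequence[float]) -> np.ndarray:
    return np.interp(ages, _DECADE_MIDPOINTS[: len(path)], path)


def _random_coalescent_newick(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Random binary (coalescent-topology) tree with exponential branch
    lengths, emitted as Newick over the given leaf labels."""
    nodes = [f"{lab}:{rng.exponential(0.5) + 0.05:.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        stem = rng.exponential(0.5) + 0.05
        nodes.append(f"({a},{b}):{stem:.6f}")
        if len(nodes) == 1:
            inner = nodes[0].rsplit(":", 1)[0]
            return inner + ";"
    return f"({nodes[0]});"


def _draw_measurements(
    ages: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw biophysical measurement columns with planted trends and
    correlated within-category blocks (Gaussian noise on the natural scale,
    truncated to plausible ranges)."""
    n = len(ages)
    out: dict[str, np.ndarray] = {}

    # tone block: ITA declines with age; colour channels derived from it
    ita = _interp_path(ages, config.tone_decline) + rng.normal(0, 4.0, n)
    b_star = np.clip(rng.normal(16.0, 1.5, n), 6.0, None)
    out["b_star"] = b_star
    out["L_star"] = np.clip(50.0 + b_star * np.tan(np.radians(ita)), 0.0, 100.0)
    out["a_star"] = rng.normal(12.0, 2.0, n)
    out["melanin_index"] = 120.0 - 1.2 * ita + rng.normal(0, 4.5, n)
    out["erythema_index"] = 90.0 - 0.8 * ita + rng.normal(0, 4.5, n)

    # elasticity block: R7 declines; R2/R5 load on it strongly, R weakly
    r7 = np.clip(
        _interp_path(ages, config.elasticity_decline) / 100.0 + rng.normal(0, 0.03, n),
        0.0, 1.5,
    )
    out["R7"] = r7
    out["R2"] = np.clip(0.92 * r7 + 0.20 + rng.normal(0, 0.030, n), 0.0, 1.5)
    out["R5"] = np.clip(0.88 * r7 + 0.10 + rng.normal(0, 0.035, n), 0.0, 1.5)
    out["R"] = np.clip(1.10 + 0.80 * r7 + rng.normal(0, 0.120, n), 0.2, 3.0)
    for name, mu, sd in (("R0", 0.30, 0.05), ("R1", 0.25, 0.05), ("R3", 0.35, 0.06),
                         ("R4", 0.28, 0.05), ("R6", 0.45, 0.07), ("R8", 0.22, 0.05),
                         ("F0", 0.60, 0.10), ("F1", 0.40, 0.08)):
        out[name] = np.clip(rng.normal(mu, sd, n), 0.0, 1.5)

    # oil: unimodal in age; hydration: flat; TEWL anti-correlates with it
    out["sebum"] = np.clip(_interp_path(ages, config.oil_path) + rng.normal(0, 5.0, n), 0.0, None)
    hydration = np.clip(rng.normal(55.0, 8.0, n), 20.0, 90.0)
    tewl = np.clip(25.0 - 0.20 * hydration + rng.normal(0, 1.5, n), 2.0, None)
    for site, offset in (("forehead", 2.0), ("cheek", -2.0)):
        for i in (1, 2, 3):
            out[f"hydration_{site}_{i}"] = hydration + offset + rng.normal(0, 2.0, n)
            out[f"tewl_{site}_{i}"] = np.clip(tewl - 0.1 * offset + rng.normal(0, 0.8, n), 1.0, None)

    # pores and wrinkles grow with age; wrinkles missing for ages < 10
    pore = 20.0 + 0.25 * ages + rng.normal(0, 5.0, n)
    out["pore_left"] = pore + rng.normal(0, 2.0, n)
    out["pore_right"] = pore + rng.normal(0, 2.0, n)
    out["pore_count"] = np.clip(5.0 + 0.40 * pore + rng.normal(0, 3.0, n), 0.0, None)
    ra = 5.0 + 0.35 * ages + rng.normal(0, 4.0, n)
    out["ra_nasolabial"] = ra + rng.normal(0, 1.5, n)
    out["ra_canthal"] = 0.75 * ra + rng.normal(0, 3.5, n)
    out["wrinkle_depth"] = np.clip(0.05 + 0.010 * ra + rng.normal(0, 0.08, n), 0.0, None)
    pediatric = ages < 10
    for col in ("ra_nasolabial", "ra_canthal", "wrinkle_depth"):
        out[col] = np.where(pediatric, np.nan, out[col])

    # remaining panel parameters (no planted structure)
    out["dermal_density"] = np.clip(1.60 - 0.004 * ages + rng.normal(0, 0.12, n), 0.3, None)
    for name, mu, sd in (("ph", 5.2, 0.4), ("gloss", 4.0, 1.2),
                         ("skin_temperature", 32.0, 0.8), ("friction", 0.45, 0.08),
                         ("desquamation", 12.0, 3.0), ("texture", 30.0, 6.0),
                         ("spot_count", 18.0, 6.0), ("uv_spot", 9.0, 3.0),
                         ("moisture_lip", 40.0, 8.0), ("tewl_hand", 11.0, 2.5)):
        out[name] = rng.normal(mu, sd, n)
    return pd.DataFrame(out)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort from the stated world (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = [f"S{i + 1:04d}" for i in range(n)]
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")

    meas = _draw_measurements(ages, config, rng)
    subjects = pd.concat(
        [pd.DataFrame({"age": ages, "sex": sex}), meas], axis=1
    )
    subjects.index = pd.Index(ids, name="subject_id")

    # microbial community: planted (sub)community -> Dirichlet-multinomial
    prof = config.profiles
    subnames = list(prof.columns)
    weights = np.array([config.subcluster_weights[c] for c in subnames])
    assign_idx = rng.choice(len(subnames), size=n, p=weights)
    subcluster = np.array([subnames[i] for i in assign_idx])
    cluster = np.array([config.cluster_of[s] for s in subcluster])
    if not config.subcluster_split:
        subcluster = cluster.copy()

    depths = np.maximum(rng.poisson(config.depth_mean, size=n), 1)
    counts = np.zeros((n, len(prof)), dtype=np.int64)
    conc = config.dirichlet_concentration
    prof_arr = prof.to_numpy()
    for i in range(n):
        p = prof_arr[:, assign_idx[i]]
        support = p > 0
        q = np.zeros_like(p)
        q[support] = rng.dirichlet(conc * p[support])
        counts[i] = rng.multinomial(depths[i], q)
    table = FeatureTable(pd.DataFrame(counts, index=ids, columns=list(prof.index)))

    tree = _random_coalescent_newick(list(prof.index), rng)
    truth = {
        "cluster": pd.Series(cluster, index=ids),
        "subcluster": pd.Series(subcluster, index=ids),
        "prevalent_genera": list(DIFFERENTIAL_GENERA) + list(HOMOGENEOUS_GENERA),
        "core_genera": list(DIFFERENTIAL_GENERA),
        "planted_crossover": {},
    }
    return SyntheticCohort(subjects=subjects, counts=table, tree=tree,
                           truth=truth, config=config)


# questionnaire category layout: 11 O, 18 S, 10 P, 20 W, 1 unscored (X)
_ITEM_TAGS = ["O"] * 11 + ["S"] * 18 + ["P"] * 10 + ["W"] * 20 + ["X"]


def simulate_responses(
    cohort: SyntheticCohort, missing_rate: float = 0.0, seed: int | None = None
) -> pd.DataFrame:
    """Questionnaire table (q01..q60 + flags + age), one row per subject.

    Item values are 1-4: each category's latent trait is the subject's
    percentile on the matching biophysical signal (oiliness <- sebum,
    pigmentation <- darker tone, wrinkle <- age/roughness; sensitivity is an
    independent latent), and item values are 1 + Binomial(3, p) draws around
    the trait.  ``missing_rate`` of cells are blanked at random.  The 60th
    item is the unscored extra of the 59-scored-item layout.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(
        seed if seed is not None else cohort.config.seed + 101
    )
    subj = cohort.subjects
    n = len(subj)

    def pct(series: pd.Series) -> np.ndarray:
        r = series.rank(method="average", na_option="keep")
        filled = r.fillna(r.mean())
        return ((filled - 0.5) / len(series)).to_numpy()

    traits = {
        "O": pct(subj["sebum"]),
        "S": rng.random(n),
        "P": pct(-pd.Series(np.degrees(np.arctan2(subj["L_star"] - 50.0, subj["b_star"])),
                            index=subj.index)),
        "W": pct(subj["ra_nasolabial"].fillna(0.0) + 0.5 * subj["age"]),
        "X": np.full(n, 0.5),
    }
    values = np.empty((n, len(_ITEM_TAGS)), dtype=float)
    for j, tag in enumerate(_ITEM_TAGS):
        p = np.clip(traits[tag] + rng.normal(0, 0.12, n), 0.05, 0.95)
        values[:, j] = 1 + rng.binomial(3, p)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan

    out = pd.DataFrame(
        values, index=subj.index,
        columns=[f"q{j + 1:02d}" for j in range(len(_ITEM_TAGS))],
    )
    out["has_listed_skin_condition"] = rng.random(n) < np.clip(0.1 + 0.4 * traits["S"], 0, 1)
    out["sun_aggravates_moles"] = rng.random(n) < 0.15
    out["age"] = subj["age"]
    out.attrs["categories"] = list(_ITEM_TAGS)
    return out


_CRITERIA = ("tone_elasticity", "oil_moisture")


def plant_crossover(
    cohort: SyntheticCohort, criterion: str, age: int,
    p_high_before: float = 0.85, p_high_after: float = 0.15,
) -> SyntheticCohort:
    """Plant an upper/lower proportion reversal at ``age`` for a criterion.

    Subjects younger than ``age`` are redrawn from a high-value regime with
    probability ``p_high_before`` and subjects at or above it with
    probability ``p_high_after``, so in expectation the above-median
    proportion dominates strictly before the planted age and is dominated
    from it onward.  The redraw touches the raw measurements behind the
    criterion's two member metrics; the planted age is recorded in
    ``truth['planted_crossover']``.  Deterministic given the cohort seed
    and the criterion name.
    """
    if criterion not in _CRITERIA:
        raise KeyError(f"unknown criterion {criterion!r}; expected one of {_CRITERIA}")
    lo, hi = cohort.config.age_range
    if not lo <= age <= hi:
        raise ValueError(f"planted age {age} outside cohort age range {cohort.config.age_range}")
    rng = np.random.default_rng(
        [cohort.config.seed, zlib.crc32(criterion.encode()), int(age)]
    )
    subjects = cohort.subjects.copy()
    n = len(subjects)
    ages = subjects["age"].to_numpy()
    high = rng.random(n) < np.where(ages < age, p_high_before, p_high_after)

    if criterion == "tone_elasticity":
        # redraw the tone and elasticity blocks coherently: dependent device
        # readouts (colour indices, the other cutometer ratios) follow the
        # new latent values just as in the generator
        ita = np.where(high, rng.normal(46.0, 2.5, n), rng.normal(33.0, 2.5, n))
        b_star = subjects["b_star"].to_numpy()
        subjects["L_star"] = np.clip(50.0 + b_star * np.tan(np.radians(ita)), 0.0, 100.0)
        subjects["melanin_index"] = 120.0 - 1.2 * ita + rng.normal(0, 4.5, n)
        subjects["erythema_index"] = 90.0 - 0.8 * ita + rng.normal(0, 4.5, n)
        r7 = np.clip(np.where(high, rng.normal(0.62, 0.02, n), rng.normal(0.40, 0.02, n)), 0.0, 1.5)
        subjects["R7"] = r7
        subjects["R2"] = np.clip(0.92 * r7 + 0.20 + rng.normal(0, 0.030, n), 0.0, 1.5)
        subjects["R5"] = np.clip(0.88 * r7 + 0.10 + rng.normal(0, 0.035, n), 0.0, 1.5)
        subjects["R"] = np.clip(1.10 + 0.80 * r7 + rng.normal(0, 0.120, n), 0.2, 3.0)
    else:
        subjects["sebum"] = np.clip(
            np.where(high, rng.normal(36.0, 3.0, n), rng.normal(8.0, 3.0, n)), 0.0, None
        )
        hydration = np.where(high, rng.normal(62.0, 3.0, n), rng.normal(47.0, 3.0, n))
        tewl = np.clip(25.0 - 0.20 * hydration + rng.normal(0, 1.5, n), 2.0, None)
        for site, offset in (("forehead", 2.0), ("cheek", -2.0)):
            for i in (1, 2, 3):
                subjects[f"hydration_{site}_{i}"] = hydration + offset + rng.normal(0, 2.0, n)
                subjects[f"tewl_{site}_{i}"] = np.clip(
                    tewl - 0.1 * offset + rng.normal(0, 0.8, n), 1.0, None
                )

    truth = dict(cohort.truth)
    truth["planted_crossover"] = {**truth.get("planted_crossover", {}), criterion: int(age)}
    return SyntheticCohort(
        subjects=subjects, counts=cohort.counts, tree=cohort.tree,
        truth=truth, config=cohort.config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write subjects CSV, feature-table TSV, tree Newick and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out / "subjects.csv",
        "features": out / "features.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    cohort.subjects.to_csv(paths["subjects"])
    cohort.counts.to_tsv(paths["features"])
    paths["tree"].write_text(cohort.tree + "\n")
    truth_json = {
        "cluster": cohort.truth["cluster"].to_dict(),
        "subcluster": cohort.truth["subcluster"].to_dict(),
        "prevalent_genera": cohort.truth["prevalent_genera"],
        "core_genera": cohort.truth["core_genera"],
        "planted_crossover": cohort.truth["planted_crossover"],
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    return paths
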