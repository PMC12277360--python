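"""Integration of biophysical skin measurements into six representative metrics.

A clinical skin panel measures dozens of parameters (hydration, TEWL, sebum,
CIELAB colour, cutometer elasticity ratios, pore size, surface roughness,
...).  Down-stream typing uses six representatives — oiliness, hydration,
skin tone (ITA), elasticity (R7), pore and wrinkle (Ra) — each normalized to
a relative 0-10 score, plus two composite criteria:

* ``tone_elasticity``  = mean(tone score, elasticity score)
* ``oil_moisture``     = mean(oiliness score, hydration score)

The reduction pipeline is: average replicate/site measurements, compute the
Individual Typology Angle from L* and b*, pick one representative per
category via within-category Pearson correlations, and rank-normalize so the
cohort mean sits at 5.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIX_METRICS",
    "DEFAULT_SCHEMA",
    "DEFAULT_CATEGORY_MAP",
    "average_replicates",
    "compute_ita",
    "correlation_matrix",
    "select_representative",
    "normalize_metrics",
    "composite_criteria",
    "build_metric_panel",
]

#: canonical metric names, in reporting order.
SIX_METRICS = ("oiliness", "hydration", "tone", "elasticity", "pore", "wrinkle")

# Raw measurement column -> collapsed parameter name.  Replicated/site
# columns (hydration, TEWL, pores) share a parameter and are averaged.
DEFAULT_SCHEMA: Mapping[str, str] = {
    **{f"hydration_forehead_{i}": "hydration" for i in (1, 2, 3)},
    **{f"hydration_cheek_{i}": "hydration" for i in (1, 2, 3)},
    **{f"tewl_forehead_{i}": "tewl" for i in (1, 2, 3)},
    **{f"tewl_cheek_{i}": "tewl" for i in (1, 2, 3)},
    "sebum": "sebum",
    "L_star": "L_star",
    "a_star": "a_star",
    "b_star": "b_star",
    "melanin_index": "melanin_index",
    "erythema_index": "erythema_index",
    "R0": "R0", "R1": "R1", "R2": "R2", "R3": "R3", "R4": "R4",
    "R5": "R5", "R6": "R6", "R7": "R7", "R8": "R8", "R": "R",
    "F0": "F0", "F1": "F1",
    "pore_left": "pore",
    "pore_right": "pore",
    "pore_count": "pore_count",
    "ra_nasolabial": "ra_nasolabial",
    "ra_canthal": "ra_canthal",
    "wrinkle_depth": "wrinkle_depth",
    "dermal_density": "dermal_density",
    "ph": "ph",
    "gloss": "gloss",
    "skin_temperature": "skin_temperature",
    "friction": "friction",
    "desquamation": "desquamation",
    "texture": "texture",
    "spot_count": "spot_count",
    "uv_spot": "uv_spot",
    "moisture_lip": "moisture_lip",
    "tewl_hand": "tewl_hand",
}

# Parameter -> target category for representative selection.  Only the six
# target categories participate; everything else is carried but not selected.
DEFAULT_CATEGORY_MAP: Mapping[str, str] = {
    "sebum": "oiliness",
    "hydration": "hydration",
    "tewl": "hydration",
    "ita": "tone",
    "melanin_index": "tone",
    "erythema_index": "tone",
    "R2": "elasticity",
    "R5": "elasticity",
    "R7": "elasticity",
    "R": "elasticity",
    "pore": "pore",
    "pore_count": "pore",
    "ra_nasolabial": "wrinkle",
    "ra_canthal": "wrinkle",
    "wrinkle_depth": "wrinkle",
}

# Default representative per category (the outcome of the selection rule on
# a cohort with the expected correlation structure).
_DEFAULT_REPRESENTATIVES: Mapping[str, str] = {
    "oiliness": "sebum",
    "hydration": "hydration",
    "tone": "ita",
    "elasticity": "R7",
    "pore": "pore",
    "wrinkle": "ra_nasolabial",
}


def average_replicates(
    raw: pd.DataFrame, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse replicate and per-site columns to per-subject parameter means.

    ``schema`` maps raw column names to parameter names; columns sharing a
    parameter are averaged (NaN-aware).  A parameter whose replicates are all
    missing for a subject stays NaN (flagged missing, never silently zero).
    Columns absent from the schema are passed through unchanged.
    """
    schema = dict(DEFAULT_SCHEMA) if schema is None else dict(schema)
    groups: dict[str, list[str]] = {}
    passthrough: list[str] = []
    for col in raw.columns:
        if col in schema:
            groups.setdefault(schema[col], []).append(col)
        elif pd.api.types.is_numeric_dtype(raw[col]):
            passthrough.append(col)
    out = pd.DataFrame(index=raw.index)
    for param, cols in groups.items():
        out[param] = raw[cols].mean(axis=1, skipna=True)
    for col in passthrough:
        out[col] = raw[col]
    return out


def compute_ita(L_star, b_star):
    """Individual Typology Angle in degrees: arctan((L*-50)/b*) * 180/pi.

    Degenerate inputs: b*=0 maps to +-90 by the sign of (L*-50), and 0 when
    both are zero.  Accepts scalars or arrays.
    """
    L = np.asarray(L_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    num = L - 50.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ita = np.degrees(np.arctan2(num, b))
    # arctan2 handles b=0 (gives +-90) and both-zero (gives 0) exactly, but
    # extends range beyond (-90, 90] for b<0; fold back to the arctan branch.
    ita = np.where(ita > 90.0, ita - 180.0, ita)
    ita = np.where(ita <= -90.0, ita + 180.0, ita)
    ita = np.where((b == 0) & (num == 0), 0.0, ita)
    ita = np.where((b == 0) & (num != 0), np.sign(num) * 90.0, ita)
    if np.ndim(L_star) == 0 and np.ndim(b_star) == 0:
        return float(ita)
    return ita


def correlation_matrix(parameters: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix over parameter columns.

    Zero-variance columns yield NaN entries (flagged undefined) rather than
    raising.  Requires at least three subjects.
    """
    if len(parameters) < 3:
        raise ValueError("correlation_matrix needs >= 3 subjects")
    num = parameters.select_dtypes(include=[np.number])
    return num.corr(method="pearson", min_periods=2)


def select_representative(
    corr: pd.DataFrame, category_map: Mapping[str, str] | None = None
) -> dict[str, str]:
    """One representative parameter per target category.

    Within each category the member maximizing the mean absolute Pearson
    correlation with the other members wins; singleton categories return
    their member; exact ties break to the lexicographically smaller name.
    On the published elasticity correlations (R7-R5 0.91, R7-R2 0.92,
    R2-R5 0.82) the rule selects R7.
    """
    category_map = dict(DEFAULT_CATEGORY_MAP) if category_map is None else dict(category_map)
    by_cat: dict[str, list[str]] = {}
    for param, cat in category_map.items():
        if param in corr.index:
            by_cat.setdefault(cat, []).append(param)
    missing = [c for c in set(category_map.values()) if c not in by_cat]
    if missing:
        raise ValueError(f"categories with no parameters present: {sorted(missing)}")
    chosen: dict[str, str] = {}
    for cat, members in sorted(by_cat.items()):
        if len(members) == 1:
            chosen[cat] = members[0]
            continue
        scores: dict[str, float] = {}
        for m in members:
            others = [o for o in members if o != m]
            vals = corr.loc[m, others].abs()
            if vals.isna().all():
                continue
            scores[m] = float(vals.mean())
        if not scores:
            raise ValueError(f"category {cat!r}: all within-category correlations undefined")
        best = max(scores.values())
        winners = sorted(m for m, s in scores.items() if math.isclose(s, best, abs_tol=1e-12))
        chosen[cat] = winners[0]
    return chosen


def normalize_metrics(values: pd.DataFrame) -> pd.DataFrame:
    """Rank-normalize each metric column to [0, 10] with cohort mean 5.

    score = 10 * (rank - 0.5) / n with average ranks for ties, so a constant
    column scores 5 everywhere and any strictly monotone transform of a
    metric leaves its scores unchanged.  NaNs stay NaN.
    """
    if len(values) < 2:
        raise ValueError("normalize_metrics needs >= 2 subjects")
    out = pd.DataFrame(index=values.index)
    for col in values.columns:
        ranks = values[col].rank(method="average", na_option="keep")
        n = values[col].notna().sum()
        out[col] = 10.0 * (ranks - 0.5) / n
    return out


def composite_criteria(normalized: pd.DataFrame) -> pd.DataFrame:
    """Two composite criteria from the normalized six-metric panel.

    ``tone_elasticity`` is the unweighted mean of the tone and elasticity
    scores; ``oil_moisture`` of the oiliness and hydration scores.  A missing
    member leaves the composite NaN (flagged) rather than imputing.
    """
    for col in ("tone", "elasticity", "oiliness", "hydration"):
        if col not in normalized.columns:
            raise KeyError(f"normalized panel lacks {col!r}")
    out = pd.DataFrame(index=normalized.index)
    te = normalized[["tone", "elasticity"]]
    om = normalized[["oiliness", "hydration"]]
    out["tone_elasticity"] = te.mean(axis=1).where(te.notna().all(axis=1))
    out["oil_moisture"] = om.mean(axis=1).where(om.notna().all(axis=1))
    return out


def build_metric_panel(
    raw: pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    category_map: Mapping[str, str] | None = None,
    select: bool = True,
) -> pd.DataFrame:
    """Full reduction: raw measurements -> six metrics + composites.

    Averages replicates, derives ITA, selects one representative per
    category (data-driven when ``select`` is true, else the standard set),
    rank-normalizes, and appends the two composite criteria.  Returns a
    frame with raw representative values (``raw_*``), normalized scores (the
    six metric names) and ``tone_elasticity`` / ``oil_moisture``.
    """
    params = average_replicates(raw, schema)
    if "L_star" in params.columns and "b_star" in params.columns:
        params["ita"] = compute_ita(params["L_star"], params["b_star"])
    if select and len(params) >= 3:
        corr = correlation_matrix(params)
        reps = select_representative(corr, category_map)
    else:
        reps = dict(_DEFAULT_REPRESENTATIVES)
    missing = [p for p in reps.values() if p not in params.columns]
    if missing:
        raise KeyError(f"representative parameters absent from data: {missing}")
    raw_vals = pd.DataFrame(
        {metric: params[reps[metric]] for metric in SIX_METRICS}, index=params.index
    )
    scores = normalize_metrics(raw_vals)
    panel = pd.concat(
        [raw_vals.add_prefix("raw_"), scores, composite_criteria(scores)], axis=1
    )
    panel.attrs["representatives"] = reps
    return panel
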