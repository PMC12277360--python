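"""Cutotype assignment (HH/HL/LH/LL), crossover detection and age strata.

Subjects are typed on two composite criteria — tone/elasticity and
oil/moisture — by cutting each at cohort tertiles: top third is H, bottom
third L, and anyone with either composite in the middle band falls in a
gray zone.  Gray-zone subjects are then reassigned H or L per composite by
comparison with the cohort mean (strictly above the mean -> H).

Aging groups come from the age-resolved proportions of subjects in the
upper vs lower tertile band of each criterion: the first age where the two
curves cross on the tone/elasticity criterion starts the Aging I group, and
the first oil/moisture crossing after the oil peak starts the Old group
(Young: age <= c1-1; Aging I: c1..c2-1; Old: age >= c2).  The final
stratification is the 12-way product {y, a, o} x {HH, HL, LH, LL}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KSC_TYPES",
    "AGING_GROUPS",
    "CrossoverReport",
    "tertile_bounds",
    "assign_type_strict",
    "reassign_gray",
    "proportion_curves",
    "detect_crossovers",
    "select_cutpoints",
    "assign_aging_group",
    "stratify",
    "assign_ksc",
]

KSC_TYPES = ("HH", "HL", "LH", "LL")
AGING_GROUPS = ("Young", "AgingI", "Old")
_GROUP_PREFIX = {"Young": "y", "AgingI": "a", "Old": "o"}


def tertile_bounds(values: Sequence[float]) -> tuple[float, float]:
    """Deterministic tertile cut values: the ceil(n/3)-th and ceil(2n/3)-th
    order statistics.  Ties share the lower band (membership is decided with
    <=, so a value equal to a bound stays below it)."""
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    n = len(v)
    if n < 3:
        raise ValueError("tertiles need >= 3 values")
    lo = v[int(np.ceil(n / 3)) - 1]
    hi = v[int(np.ceil(2 * n / 3)) - 1]
    return float(lo), float(hi)


def _band(values: pd.Series, bounds: tuple[float, float]) -> pd.Series:
    """L/M/H band per value; ties share the lower band."""
    lo, hi = bounds
    out = pd.Series("M", index=values.index, dtype=object)
    out[values <= lo] = "L"
    out[values > hi] = "H"
    out[values.isna()] = np.nan
    return out


def assign_type_strict(composites: pd.DataFrame) -> pd.Series:
    """Tertile-based strict type: HH/HL/LH/LL or GRAY.

    ``composites`` must carry ``tone_elasticity`` and ``oil_moisture``.  A
    subject with either composite in the middle tertile band is GRAY.  The
    first letter is the tone/elasticity call.  Constant composites put
    everyone in the gray zone (a warning-level degenerate case for callers).
    """
    te = composites["tone_elasticity"]
    om = composites["oil_moisture"]
    bands_te = _band(te, tertile_bounds(te))
    bands_om = _band(om, tertile_bounds(om))
    out = pd.Series(index=composites.index, dtype=object)
    for idx in composites.index:
        bt, bo = bands_te[idx], bands_om[idx]
        if pd.isna(bt) or pd.isna(bo):
            out[idx] = np.nan
        elif bt == "M" or bo == "M":
            out[idx] = "GRAY"
        else:
            out[idx] = ("H" if bt == "H" else "L") + ("H" if bo == "H" else "L")
    return out


def reassign_gray(strict: pd.Series, composites: pd.DataFrame) -> pd.Series:
    """Resolve GRAY subjects by the cohort mean: strictly above -> H, else L.

    Non-gray subjects keep their strict type.  The mean is taken over the
    whole cohort per composite.
    """
    mean_te = composites["tone_elasticity"].mean()
    mean_om = composites["oil_moisture"].mean()
    out = strict.copy()
    gray = strict == "GRAY"
    te_letter = np.where(composites.loc[gray, "tone_elasticity"] > mean_te, "H", "L")
    om_letter = np.where(composites.loc[gray, "oil_moisture"] > mean_om, "H", "L")
    out[gray] = [t + o for t, o in zip(te_letter, om_letter)]
    return out


@dataclass
class CrossoverReport:
    """Age-resolved band proportions and detected crossings for a criterion."""

    criterion: str
    ages: np.ndarray                 # ages with >= 1 subject, ascending
    upper: np.ndarray                # smoothed fraction in the top band
    lower: np.ndarray                # smoothed fraction in the bottom band
    middle: np.ndarray
    crossovers: list[int] = field(default_factory=list)
    directions: list[str] = field(default_factory=list)  # per crossover

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "upper": self.upper, "lower": self.lower,
             "middle": self.middle}
        ).set_index("age")


def proportion_curves(
    values: pd.Series,
    ages: pd.Series,
    criterion: str = "criterion",
    window: int = 3,
) -> CrossoverReport:
    """Per-age fractions of subjects in the upper/lower/middle tertile band.

    Bands are cut on the whole cohort; fractions are computed per single
    year of age (empty ages are excluded) and smoothed with a centered
    moving average of ``window`` points (``window=1`` is the identity).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    ok = values.notna() & ages.notna()
    values, ages = values[ok], ages[ok].astype(int)
    bands = _band(values, tertile_bounds(values))
    tab = pd.crosstab(ages, bands, normalize="index")
    for b in ("L", "M", "H"):
        if b not in tab.columns:
            tab[b] = 0.0
    tab = tab.sort_index()
    smoothed = tab.rolling(window, center=True, min_periods=1).mean()
    return CrossoverReport(
        criterion=criterion,
        ages=tab.index.to_numpy(),
        upper=smoothed["H"].to_numpy(),
        lower=smoothed["L"].to_numpy(),
        middle=smoothed["M"].to_numpy(),
    )


def detect_crossovers(report: CrossoverReport, persistence: int = 2) -> list[int]:
    """Ages where the upper/lower proportion ordering flips.

    A crossing at age ``a`` requires the ordering of the two curves to flip
    relative to the last *established* ordering and the new ordering to
    persist for the next ``persistence`` observed ages (truncated at the
    range end).  A transient blip that fails the persistence check does not
    reset the established ordering, so its end is not itself a crossing.
    Both directions are reported (the report records which); ties count as
    the lower curve having caught up.
    """
    ages, up, lo = report.ages, report.upper, report.lower
    if len(ages) < 3:
        raise ValueError("crossover detection needs curves over >= 3 ages")
    found: list[int] = []
    directions: list[str] = []
    state = np.where(lo - up >= 0, 1, -1)  # +1: lower band dominates or ties
    established = int(state[0])
    for i in range(1, len(ages)):
        if state[i] == established:
            continue
        horizon = state[i : i + 1 + persistence]
        if np.all(horizon == state[i]):
            found.append(int(ages[i]))
            directions.append(
                "lower_over_upper" if state[i] == 1 else "upper_over_lower"
            )
            established = int(state[i])
    report.crossovers = found
    report.directions = directions
    return found


def select_cutpoints(
    tone_report: CrossoverReport,
    oil_report: CrossoverReport,
    persistence: int = 2,
) -> tuple[int, int]:
    """Aging-group cutpoints (c1, c2) from the two criterion reports.

    c1 is the first tone/elasticity crossing.  c2 is the first oil/moisture
    crossing after the age of maximal smoothed upper-band oil proportion
    (the oil peak), reflecting that oil rises into the 20s-30s and the
    meaningful decline crossing comes after the peak.  Requires c2 > c1.
    """
    tone_x = tone_report.crossovers or detect_crossovers(tone_report, persistence)
    oil_x = oil_report.crossovers or detect_crossovers(oil_report, persistence)
    if not tone_x:
        raise ValueError("no tone/elasticity crossover found")
    if not oil_x:
        raise ValueError("no oil/moisture crossover found")
    c1 = tone_x[0]
    peak_age = int(oil_report.ages[int(np.argmax(oil_report.upper))])
    after_peak = [a for a in oil_x if a > peak_age]
    if not after_peak:
        raise ValueError(
            f"no oil crossing after the oil peak at age {peak_age}: {oil_x}"
        )
    c2 = after_peak[0]
    if c2 <= c1:
        raise ValueError(f"cutpoints out of order: c1={c1}, c2={c2}")
    return c1, c2


def assign_aging_group(age: float, c1: int, c2: int) -> str:
    """Young iff age <= c1-1, AgingI iff c1 <= age <= c2-1, Old iff age >= c2."""
    if c1 >= c2:
        raise ValueError("c1 must be < c2")
    if age < 0:
        raise ValueError("negative age")
    if age <= c1 - 1:
        return "Young"
    if age <= c2 - 1:
        return "AgingI"
    return "Old"


def stratify(final_type: str, aging_group: str) -> str:
    """12-way stratum label: aging prefix (y/a/o) + final type (e.g. oLL)."""
    if final_type not in KSC_TYPES:
        raise ValueError(f"unknown type {final_type!r}")
    return _GROUP_PREFIX[aging_group] + final_type


def assign_ksc(
    composites: pd.DataFrame,
    ages: pd.Series,
    c1: int = 35,
    c2: int = 51,
) -> pd.DataFrame:
    """Full labeling: strict type, gray reassignment, aging group, stratum.

    Default cutpoints are 35/51; pass detected values to use cohort-derived
    boundaries.  Returns a frame with ``strict_type``, ``final_type``,
    ``aging_group`` and ``strata`` columns.
    """
    strict = assign_type_strict(composites)
    final = reassign_gray(strict, composites)
    groups = ages.map(lambda a: assign_aging_group(a, c1, c2))
    strata = pd.Series(
        [stratify(t, g) for t, g in zip(final, groups)], index=composites.index
    )
    return pd.DataFrame(
        {"strict_type": strict, "final_type": final,
         "aging_group": groups, "strata": strata}
    )
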