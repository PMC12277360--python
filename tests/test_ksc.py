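"""Cutotype assignment, gray-zone reassignment, crossover detection and
age stratification."""

import numpy as np
import pandas as pd
import pytest

from kscope import biophys, ksc
from kscope.synthetic import CohortConfig, plant_crossover, simulate_cohort


def composites(te, om=None):
    te = pd.Series(te, dtype=float)
    om = te.copy() if om is None else pd.Series(om, dtype=float)
    return pd.DataFrame({"tone_elasticity": te, "oil_moisture": om})


def brute_force_bands(values):
    """Independent tertile oracle: sort and cut at the ceil(n/3) order
    statistics, ties to the lower band."""
    v = sorted(values)
    n = len(v)
    lo, hi = v[int(np.ceil(n / 3)) - 1], v[int(np.ceil(2 * n / 3)) - 1]
    return ["L" if x <= lo else ("H" if x > hi else "M") for x in values]


class TestAssignTypeStrict:
    def test_corner_types(self):
        comp = composites([1, 2, 3, 4, 5, 6, 7, 8, 9])
        out = ksc.assign_type_strict(comp)
        # both axes equal: top tertile -> HH, bottom -> LL, middle -> GRAY
        assert list(out) == ["LL"] * 3 + ["GRAY"] * 3 + ["HH"] * 3

    def test_gray_on_either_axis(self):
        comp = composites([9, 5, 1], [9, 9, 9])
        comp = pd.concat([comp, composites([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])])
        comp.index = range(len(comp))
        out = ksc.assign_type_strict(comp)
        assert out[1] == "GRAY"  # middle tone band forces gray

    @pytest.mark.parametrize("n", [7, 12, 23, 30])
    def test_tertile_oracle(self, n, rng):
        """Agrees with the brute-force sort-and-cut on small cohorts."""
        te = rng.normal(size=n)
        om = rng.normal(size=n)
        out = ksc.assign_type_strict(composites(te, om))
        bte, bom = brute_force_bands(te), brute_force_bands(om)
        for i in range(n):
            if bte[i] == "M" or bom[i] == "M":
                assert out[i] == "GRAY"
            else:
                assert out[i] == ("H" if bte[i] == "H" else "L") + (
                    "H" if bom[i] == "H" else "L"
                )


class TestReassignGray:
    def test_rules(self):
        comp = composites([1, 2, 5.1, 9, 10], [1, 2, 5.1, 9, 10])
        strict = pd.Series(["LL", "LL", "GRAY", "HH", "HH"])
        out = ksc.reassign_gray(strict, comp)
        assert out[2] == "LL"  # 5.1 < mean 5.42 on both axes
        assert (out.drop(2) == strict.drop(2)).all()  # non-gray unchanged

    def test_at_mean_goes_low(self):
        comp = composites([0.0, 5.0, 10.0], [0.0, 6.0, 10.0])
        strict = pd.Series(["LL", "GRAY", "HH"])
        out = ksc.reassign_gray(strict, comp)
        # tone exactly at the mean -> L (strictly-above rule); oil above -> H
        assert out[1] == "LH"


class TestProportionCurves:
    def test_direct_fractions_w1(self):
        # age-30 bin: 4 upper, 1 lower, 0 middle; the rest of the cohort
        # pins the tertile bounds at 1 (lower) and 5 (middle)
        te = pd.Series([9.0] * 4 + [1.0] + [1.0] * 14 + [5.0] * 12 + [9.0] * 8)
        ages = pd.Series([30] * 5 + [40] * 17 + [41] * 17)
        rep = ksc.proportion_curves(te, ages, window=1)
        at30 = rep.to_frame().loc[30]
        assert at30["upper"] == pytest.approx(0.8)
        assert at30["lower"] == pytest.approx(0.2)
        assert at30["middle"] == 0.0

    def test_window_one_is_identity_of_window_three_smoothing(self, rng):
        te = pd.Series(rng.normal(size=200))
        ages = pd.Series(rng.integers(20, 30, size=200))
        r1 = ksc.proportion_curves(te, ages, window=1)
        r3 = ksc.proportion_curves(te, ages, window=3)
        assert not np.allclose(r1.upper, r3.upper)  # smoothing does act
        assert np.allclose(
            r3.upper[1:-1],
            (r1.upper[:-2] + r1.upper[1:-1] + r1.upper[2:]) / 3,
        )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ksc.proportion_curves(pd.Series([1.0, 2.0]), pd.Series([1, 2]), window=2)


class TestDetectCrossovers:
    def make_report(self, upper, lower):
        ages = np.arange(len(upper))
        return ksc.CrossoverReport("c", ages, np.array(upper, float),
                                   np.array(lower, float),
                                   1 - np.array(upper) - np.array(lower))

    def test_monotone_no_crossing(self):
        rep = self.make_report([0.8] * 6, [0.1] * 6)
        assert ksc.detect_crossovers(rep) == []

    def test_single_and_double_crossing(self):
        rep = self.make_report([0.8, 0.8, 0.2, 0.2, 0.2], [0.1, 0.1, 0.7, 0.7, 0.7])
        assert ksc.detect_crossovers(rep) == [2]
        # oil-like: lower dominates, then upper (age 2), then lower again (age 6)
        up = [0.2, 0.2, 0.7, 0.7, 0.7, 0.7, 0.2, 0.2, 0.2]
        lo = [0.7, 0.7, 0.2, 0.2, 0.2, 0.2, 0.7, 0.7, 0.7]
        rep2 = self.make_report(up, lo)
        assert ksc.detect_crossovers(rep2) == [2, 6]
        assert rep2.directions == ["upper_over_lower", "lower_over_upper"]

    def test_persistence_filters_blips(self):
        rep = self.make_report([0.8, 0.2, 0.8, 0.8, 0.8], [0.1, 0.7, 0.1, 0.1, 0.1])
        assert ksc.detect_crossovers(rep, persistence=2) == []


class TestSelectCutpoints:
    def test_tone_oil_combination(self):
        ages = np.arange(10, 60)
        tone = ksc.CrossoverReport(
            "tone", ages, np.where(ages < 35, 0.7, 0.2).astype(float),
            np.where(ages < 35, 0.2, 0.7).astype(float), np.zeros(len(ages)))
        # oil rises to a peak near 30 then declines; crossings at 14 and 51
        up = np.where((ages >= 14) & (ages < 51), 0.6, 0.15).astype(float)
        up[ages == 30] = 0.8
        oil = ksc.CrossoverReport("oil", ages, up, 0.75 - up, np.full(len(ages), 0.25))
        assert ksc.select_cutpoints(tone, oil) == (35, 51)

    def test_no_crossing_after_peak_errors(self):
        ages = np.arange(0, 40)
        tone = ksc.CrossoverReport(
            "tone", ages, np.where(ages < 20, 0.7, 0.2).astype(float),
            np.where(ages < 20, 0.2, 0.7).astype(float), np.zeros(len(ages)))
        up = np.where(ages >= 14, 0.6, 0.15).astype(float)
        up[ages == 35] = 0.9   # peak after the only crossing
        oil = ksc.CrossoverReport("oil", ages, up, 0.75 - up, np.full(len(ages), 0.25))
        with pytest.raises(ValueError):
            ksc.select_cutpoints(tone, oil)


class TestAgingGroups:
    @pytest.mark.parametrize(
        "age,expected",
        [(34, "Young"), (35, "AgingI"), (50, "AgingI"), (51, "Old"),
         (0, "Young"), (88, "Old")],
    )
    def test_boundaries(self, age, expected):
        assert ksc.assign_aging_group(age, 35, 51) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            ksc.assign_aging_group(-1, 35, 51)
        with pytest.raises(ValueError):
            ksc.assign_aging_group(20, 51, 35)

    def test_stratify(self):
        assert ksc.stratify("LL", "Old") == "oLL"
        assert ksc.stratify("HL", "Young") == "yHL"
        with pytest.raises(ValueError):
            ksc.stratify("GRAY", "Old")


class TestAssignKsc:
    def test_partition_into_12_strata(self, cohort300):
        panel = biophys.build_metric_panel(cohort300.subjects)
        labels = ksc.assign_ksc(
            panel[["tone_elasticity", "oil_moisture"]], cohort300.subjects["age"]
        )
        assert labels["final_type"].isin(ksc.KSC_TYPES).all()
        assert (labels["strata"].value_counts().sum()) == len(labels)
        valid = {p + t for p in "yao" for t in ksc.KSC_TYPES}
        assert set(labels["strata"]) <= valid


class TestPlantedCrossoverRecovery:
    def test_modal_detection_at_35(self):
        """Over seeded cohorts with a planted tone reversal at 35, the
        modal first detected lower-over-upper crossing is 35."""
        firsts = []
        for seed in range(1, 6):
            c = simulate_cohort(CohortConfig(n_subjects=2000, seed=seed))
            c = plant_crossover(c, "tone_elasticity", 35)
            panel = biophys.build_metric_panel(c.subjects)
            rep = ksc.proportion_curves(
                panel["tone_elasticity"], c.subjects["age"], "tone_elasticity"
            )
            xs = ksc.detect_crossovers(rep)
            lows = [a for a, d in zip(xs, rep.directions) if d == "lower_over_upper"]
            firsts.append(lows[0] if lows else None)
        assert pd.Series(firsts).mode()[0] == 35
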