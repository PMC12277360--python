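"""Rank statistics, PERMANOVA, core-genus selection, effect sizes,
pairwise differential matrices and pathway filtering."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from kscope.microbiome import (
    FeatureTable,
    clr_transform,
    core_genus_selection,
    filter_pathway_table,
    kruskal_wallis,
    lda_effect_size,
    pairwise_differential,
    permanova,
    rarefy,
)


class TestKruskalWallis:
    def test_hand_computed(self):
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert h == pytest.approx(3.857142857, abs=1e-6)

    def test_symmetry_and_scipy_oracle(self, rng):
        groups = [rng.normal(size=8), rng.normal(0.5, 1, size=9), rng.normal(size=7)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2)
        ref = sps.kruskal(*groups)
        assert h1 == pytest.approx(ref.statistic)
        assert p1 == pytest.approx(ref.pvalue)

    def test_ties_against_scipy(self, rng):
        groups = [rng.integers(0, 4, size=10).astype(float) for _ in range(3)]
        ref = sps.kruskal(*groups)
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(ref.statistic)

    def test_all_tied(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(4)])
        assert (h, p) == (0.0, 1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0])])


class TestPermanova:
    def test_matches_skbio(self, rng):
        from skbio.stats.distance import permanova as skbio_permanova

        X = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(1.2, 1, (13, 3))])
        dist = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(25)])
        labels = ["a"] * 12 + ["b"] * 13
        f, p = permanova(dist, labels, n_perm=999, seed=0)
        ref = skbio_permanova(dist, labels, permutations=999, seed=0)
        assert f == pytest.approx(float(ref["test statistic"]))

    def test_perfect_separation_min_p(self, rng):
        X = np.vstack([rng.normal(0, 0.01, (10, 2)), rng.normal(50, 0.01, (10, 2))])
        dist = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(20)])
        _, p = permanova(dist, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_relabeling_keeps_f(self, rng):
        X = rng.normal(size=(20, 2))
        dist = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(20)])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        f1, _ = permanova(dist, labels, n_perm=49, seed=0)
        f2, _ = permanova(dist, np.where(labels == "a", "b", "a"), n_perm=49, seed=0)
        assert f1 == pytest.approx(f2)

    def test_type_one_error_rate(self):
        """With labels independent of structure, rejection at 0.05 stays
        near nominal (<= 0.1 over 50 seeded datasets)."""
        rejections = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 3))
            dist = DistanceMatrix(squareform(pdist(X)),
                                  ids=[str(i) for i in range(24)])
            labels = np.array(["a"] * 12 + ["b"] * 12)
            _, p = permanova(dist, labels, n_perm=999, seed=seed + 1000)
            rejections += p <= 0.05
        assert rejections / 50 <= 0.1


class TestCoreGenusSelection:
    def test_planted_recovery(self, cohort300):
        table = rarefy(cohort300.counts, 1391, seed=1)
        rep = core_genus_selection(table, cohort300.truth["subcluster"])
        assert len(rep.prevalent) == 17
        assert set(rep.prevalent) == set(cohort300.truth["prevalent_genera"])
        assert set(rep.core) == set(cohort300.truth["core_genera"])
        assert len(rep.core) == 15

    def test_core_subset_of_prevalent_and_alpha_monotone(self, cohort300):
        table = rarefy(cohort300.counts, 1391, seed=2)
        rep = core_genus_selection(table, cohort300.truth["subcluster"])
        assert set(rep.core) <= set(rep.prevalent)
        stricter = core_genus_selection(
            table, cohort300.truth["subcluster"], alpha=0.001
        )
        assert set(stricter.core) <= set(rep.core)

    def test_prevalence_threshold_edge(self):
        # genus B detected in 49 of 100 samples -> excluded at 50%
        counts = pd.DataFrame(
            {"A": np.full(100, 10),
             "B": np.r_[np.ones(49, int), np.zeros(51, int)]},
            index=[f"s{i}" for i in range(100)],
        )
        labels = pd.Series(["x"] * 50 + ["y"] * 50, index=counts.index)
        rep = core_genus_selection(FeatureTable(counts), labels)
        assert "B" not in rep.prevalent and "A" in rep.prevalent

    def test_identical_distributions_empty_core(self, rng):
        counts = pd.DataFrame(rng.integers(5, 20, size=(40, 3)),
                              index=[f"s{i}" for i in range(40)],
                              columns=["A", "B", "C"])
        labels = pd.Series(["x", "y"] * 20, index=counts.index)
        rep = core_genus_selection(FeatureTable(counts), labels, alpha=0.01)
        assert rep.core == []

    def test_cumulative_abundance_mode(self, cohort300):
        rep = core_genus_selection(
            cohort300.counts, cohort300.truth["subcluster"],
            mode="cumulative-abundance",
        )
        rel = cohort300.counts.relative_abundance()
        means = rel.mean().sort_values(ascending=False)
        assert means[rep.prevalent].sum() >= 0.5
        assert rep.prevalent  # non-empty

    def test_single_subcluster_errors(self, toy_table):
        labels = pd.Series(["x"] * 4, index=toy_table.counts.index)
        with pytest.raises(ValueError):
            core_genus_selection(toy_table, labels)


class TestLdaEffectSize:
    def make_table(self, rng, enriched_factor=100.0, n=100):
        base = rng.integers(50, 100, size=(n, 4)).astype(float)
        labels = pd.Series(["young"] * (n // 2) + ["old"] * (n // 2),
                           index=[f"s{i}" for i in range(n)])
        base[: n // 2, 0] *= enriched_factor      # genus G0 enriched in young
        counts = pd.DataFrame(base.astype(int), index=labels.index,
                              columns=["G0", "G1", "G2", "G3"])
        return FeatureTable(counts), labels

    def test_planted_enrichment_recovered(self, rng):
        table, labels = self.make_table(rng)
        out = lda_effect_size(table, labels, seed=0)
        assert "G0" in set(out["feature"])
        row = out[out["feature"] == "G0"].iloc[0]
        assert row["enriched_class"] == "young"
        assert row["lda_score"] >= 2.0

    def test_label_swap_antisymmetry(self, rng):
        table, labels = self.make_table(rng)
        out1 = lda_effect_size(table, labels, seed=0)
        swapped = labels.map({"young": "old", "old": "young"})
        out2 = lda_effect_size(table, swapped, seed=0)
        r1 = out1[out1["feature"] == "G0"].iloc[0]
        r2 = out2[out2["feature"] == "G0"].iloc[0]
        assert r1["enriched_class"] == "young" and r2["enriched_class"] == "old"
        assert r1["lda_score"] == pytest.approx(r2["lda_score"], rel=0.05)

    def test_flat_feature_screened_out(self, rng):
        counts = pd.DataFrame(
            {"A": np.full(30, 50), "B": rng.integers(40, 60, 30)},
            index=[f"s{i}" for i in range(30)],
        )
        labels = pd.Series(["x", "y"] * 15, index=counts.index)
        out = lda_effect_size(FeatureTable(counts), labels, seed=0)
        assert "A" not in set(out["feature"])

    def test_small_class_warning(self, rng):
        table, labels = self.make_table(rng, n=20)
        labels.iloc[:2] = "tiny"
        labels.iloc[2:] = ["young", "old"] * 9
        with pytest.warns(UserWarning, match="tiny"):
            lda_effect_size(table, labels, seed=0)


class TestPairwiseDifferential:
    def test_identical_strata_near_zero(self, rng):
        counts = pd.DataFrame(rng.integers(10, 30, size=(40, 2)),
                              index=[f"s{i}" for i in range(40)],
                              columns=["A", "B"])
        labels = pd.Series(["x", "y"] * 20, index=counts.index)
        mats, masks = pairwise_differential(FeatureTable(counts), labels)
        assert abs(mats["A"].loc["x", "y"]) < 1.0
        assert not masks["A"].to_numpy().any()

    def test_planted_shift_sign_and_mask(self, rng):
        a = rng.integers(200, 300, size=25)
        b = rng.integers(5, 15, size=25)
        counts = pd.DataFrame(
            {"G": np.r_[a, b], "H": rng.integers(50, 60, 50)},
            index=[f"s{i}" for i in range(50)],
        )
        labels = pd.Series(["hi"] * 25 + ["lo"] * 25, index=counts.index)
        mats, masks = pairwise_differential(FeatureTable(counts), labels)
        assert mats["G"].loc["hi", "lo"] > 1.0        # enriched in hi
        assert masks["G"].loc["hi", "lo"]
        assert mats["G"].loc["lo", "hi"] == pytest.approx(-mats["G"].loc["hi", "lo"])

    def test_antisymmetric_three_strata(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 2)),
                              index=[f"s{i}" for i in range(30)],
                              columns=["A", "B"])
        labels = pd.Series(["x", "y", "z"] * 10, index=counts.index)
        mats, _ = pairwise_differential(FeatureTable(counts), labels)
        m = mats["A"]
        assert np.allclose(m.to_numpy(), -m.to_numpy().T)

    def test_clr_rows_centered(self, toy_table):
        clr = clr_transform(toy_table.counts)
        assert np.allclose(clr.mean(axis=1), 0.0)


class TestFilterPathwayTable:
    def test_threshold_dedupe_zscore(self):
        df = pd.DataFrame(
            [[0.004, 0.004], [0.02, 0.02], [0.3, 0.1], [0.3, 0.2]],
            index=["low", "const", "dup", "dup"],
            columns=["s1", "s2"],
        )
        out = filter_pathway_table(df)
        assert "low" not in out.index               # mean 0.004 < 0.5%
        assert (out.index == ["const", "dup"]).all()  # first duplicate kept
        z = filter_pathway_table(df, zscore=True)
        assert (z.loc["const"] == 0.0).all()        # constant row -> 0
        assert z.loc["dup"].mean() == pytest.approx(0.0)
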