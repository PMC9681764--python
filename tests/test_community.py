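"""Abundance normalization, MAG rules, and ecological statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio.stats.distance import DistanceMatrix
import skbio.stats.distance as sksd

from halocline.community import (
    anosim,
    archaea_bacteria_ratio,
    bray_curtis,
    dereplicate_species,
    filter_mags,
    normalize_relative_abundance,
    pcoa,
    select_specialized_mags,
    welch_t,
)
from halocline.types import AbundanceTable, MAGRecord


class TestNormalization:
    def test_single_feature_becomes_100(self):
        t = normalize_relative_abundance(pd.DataFrame({"s": [7.0]}, index=["f"]),
                                         {"s": "a"})
        assert t.values.loc["f", "s"] == 100.0

    def test_hand_example(self):
        t = normalize_relative_abundance(
            pd.DataFrame({"s": [2.0, 3.0, 5.0]}, index=list("abc")), {"s": "x"}
        )
        assert t.values["s"].tolist() == [20.0, 30.0, 50.0]

    def test_idempotent(self):
        counts = pd.DataFrame({"s1": [1.0, 4.0], "s2": [2.0, 2.0]}, index=["a", "b"])
        t1 = normalize_relative_abundance(counts, {"s1": "x", "s2": "y"})
        t2 = normalize_relative_abundance(t1.values, t1.sites)
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_zero_sample_named_in_error(self):
        counts = pd.DataFrame({"ok": [1.0], "empty": [0.0]}, index=["a"])
        with pytest.raises(ValueError, match="empty"):
            normalize_relative_abundance(counts, {"ok": "x", "empty": "x"})


class TestRatios:
    def make(self, arch, bact):
        values = pd.DataFrame({"s": [arch, bact]}, index=["a1", "b1"])
        tax = pd.DataFrame({"domain": ["Archaea", "Bacteria"],
                            "phylum": ["E", "B"]}, index=["a1", "b1"])
        return AbundanceTable(values, {"s": "site"}, tax)

    def test_even_split_is_one(self):
        per_sample, per_site = archaea_bacteria_ratio(self.make(50.0, 50.0))
        assert per_sample["s"] == 1.0 and per_site["site"] == 1.0

    def test_four_to_one(self):
        per_sample, _ = archaea_bacteria_ratio(self.make(80.0, 20.0))
        assert per_sample["s"] == pytest.approx(4.0)

    def test_feature_order_invariance(self, toy_table):
        r1, _ = archaea_bacteria_ratio(toy_table)
        shuffled = AbundanceTable(
            toy_table.values.iloc[::-1], toy_table.sites,
            toy_table.taxonomy.iloc[::-1],
        )
        r2, _ = archaea_bacteria_ratio(shuffled)
        pd.testing.assert_series_equal(r1, r2)

    def test_zero_bacteria_reports_inf(self):
        per_sample, _ = archaea_bacteria_ratio(self.make(100.0, 0.0))
        assert np.isinf(per_sample["s"])


class TestMagRules:
    def test_quality_bounds_inclusive(self):
        kept = filter_mags([MAGRecord("m", 70.0, 5.0)])
        assert len(kept) == 1
        assert filter_mags([MAGRecord("m", 69.9, 0.0)]) == []

    def test_toy_quality_set(self):
        mags = [MAGRecord(f"m{i}", c, x) for i, (c, x) in
                enumerate([(90, 1), (75, 6), (60, 0), (70, 5), (95, 4.9)])]
        assert len(filter_mags(mags)) == 3

    def test_no_edges_every_mag_own_species(self):
        mags = [MAGRecord("a", 90, 0), MAGRecord("b", 80, 0)]
        res = dereplicate_species(mags, pd.DataFrame(columns=["id1", "id2", "ani", "coverage"]))
        assert res.n_species == 2

    def test_single_linkage_chain(self):
        mags = [MAGRecord("a", 90, 0), MAGRecord("b", 80, 0), MAGRecord("c", 85, 0)]
        pairs = pd.DataFrame(
            {"id1": ["a", "b"], "id2": ["b", "c"], "ani": [96.0, 97.0],
             "coverage": [50.0, 50.0]}
        )
        res = dereplicate_species(mags, pairs)
        assert res.clusters == [["a", "b", "c"]]
        assert res.representatives == ["a"]  # highest completeness - 5*contamination

    def test_threshold_boundary_inclusive(self):
        mags = [MAGRecord("a", 90, 0), MAGRecord("b", 80, 0)]
        pairs = pd.DataFrame({"id1": ["a"], "id2": ["b"], "ani": [95.0],
                              "coverage": [10.0]})
        assert dereplicate_species(mags, pairs).n_species == 1
        pairs.loc[0, "ani"] = 94.99
        assert dereplicate_species(mags, pairs).n_species == 2

    def test_specialized_selection_strict_cutoff(self):
        values = pd.DataFrame(
            {"a_1": [18.0, 10.0, 72.0], "a_2": [18.0, 10.0, 72.0],
             "b_1": [2.0, 10.0, 88.0]},
            index=["mag_hi", "mag_edge", "mag_rest"],
        )
        sites = {"a_1": "a", "a_2": "a", "b_1": "b"}
        t = AbundanceTable(values, sites)
        assert select_specialized_mags(t) == ["mag_hi", "mag_rest"]

    def test_specialized_matches_brute_force(self, toy_table):
        got = set(select_specialized_mags(toy_table, 25.0))
        means = {f: {} for f in toy_table.features}
        for f in toy_table.features:
            for site, cols in toy_table.samples_by_site().items():
                means[f][site] = toy_table.values.loc[f, cols].mean()
        expect = {f for f, m in means.items() if any(v > 25.0 for v in m.values())}
        assert got == expect


class TestBrayCurtis:
    def test_hand_example_3_over_11(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 2.0, 1.0]})
        assert bray_curtis(df)["x", "y"] == pytest.approx(3 / 11)

    def test_identical_samples_distance_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        assert bray_curtis(df)["x", "y"] == 0.0

    def test_disjoint_supports_distance_one(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 3.0]})
        assert bray_curtis(df)["x", "y"] == 1.0

    def test_axioms_and_feature_permutation_invariance(self, toy_table):
        dm = bray_curtis(toy_table)
        d = dm.data
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0 and d.max() <= 1
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(toy_table.features))
        shuffled = AbundanceTable(toy_table.values.iloc[perm], toy_table.sites,
                                  toy_table.taxonomy.iloc[perm])
        assert np.allclose(bray_curtis(shuffled).data, d)


class TestPCoA:
    def test_collinear_points_single_dominant_axis(self):
        x = np.array([[0.0], [1.0], [3.0], [6.0]])
        dm = DistanceMatrix(squareform(pdist(x)), list("abcd"))
        res = pcoa(dm)
        assert res.proportion_explained[0] == pytest.approx(1.0)
        recon = pdist(res.coordinates.values[:, :1])
        assert np.max(np.abs(recon - pdist(x))) < 1e-8

    def test_degenerate_all_equal_points(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        res = pcoa(dm)
        assert np.allclose(res.coordinates.values, 0.0)

    def test_two_dimensional_euclidean_fully_captured(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(7, 2))
        dm = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(7)])
        res = pcoa(dm)
        assert res.proportion_explained[:2].sum() == pytest.approx(1.0, abs=1e-10)
        recon = pdist(res.coordinates.values[:, :2])
        assert np.max(np.abs(recon - pdist(x))) < 1e-8

    def test_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        dm = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(6)])
        res = pcoa(dm)
        ref = __import__("skbio.stats.ordination", fromlist=["pcoa"]).pcoa(dm)
        assert np.allclose(res.eigenvalues,
                           ref.eigvals.values[ref.eigvals.values > 1e-10], atol=1e-8)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            pcoa(dm)


def separated_distance_matrix(seed=0, n_per=3, shift=5.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2 * n_per, 2))
    x[n_per:] += shift
    ids = [f"s{i}" for i in range(2 * n_per)]
    return DistanceMatrix(squareform(pdist(x)), ids), ["g1"] * n_per + ["g2"] * n_per


class TestAnosim:
    def test_full_separation_gives_r_one(self):
        dm, groups = separated_distance_matrix(shift=50.0)
        res = anosim(dm, groups, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_r_matches_skbio(self):
        dm, groups = separated_distance_matrix(seed=5, shift=1.0)
        res = anosim(dm, groups, n_permutations=9, seed=0)
        ref = sksd.anosim(dm, grouping=groups, permutations=9)
        assert res.r == pytest.approx(ref["test statistic"])

    def test_exact_enumeration_matches_brute_force(self):
        dm, groups = separated_distance_matrix(seed=2, shift=1.5)
        res = anosim(dm, groups, exact=True)
        # independent oracle: re-rank and enumerate all 720 relabelings
        ranks = rankdata(squareform(dm.data, checks=False))
        pairs = list(itertools.combinations(range(6), 2))

        def r_of(lab):
            w = np.array([lab[i] == lab[j] for i, j in pairs])
            return (ranks[~w].mean() - ranks[w].mean()) / (6 * 5 / 4)

        obs = r_of(groups)
        count = sum(
            r_of(list(p)) >= obs - 1e-12
            for p in itertools.permutations(groups)
        )
        assert res.r == pytest.approx(obs)
        assert res.p_value == pytest.approx((1 + count) / (1 + 720))

    def test_null_mean_r_near_zero(self):
        rs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(8, 2))  # i.i.d., labels arbitrary
            dm = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(8)])
            res = anosim(dm, ["a"] * 4 + ["b"] * 4, n_permutations=0, seed=seed)
            rs.append(res.r)
        assert abs(np.mean(rs)) < 0.05
        assert all(-1.0 - 1e-9 <= r <= 1.0 + 1e-9 for r in rs)

    def test_degenerate_grouping_rejected(self):
        dm, _ = separated_distance_matrix()
        with pytest.raises(ValueError):
            anosim(dm, ["a"] * 5 + ["b"], n_permutations=9)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_example(self):
        res = welch_t([1, 2, 3], [2, 4, 6])
        assert res.t == pytest.approx(-1.549, abs=5e-4)
        assert res.df == pytest.approx(2.941, abs=5e-4)

    def test_swap_negates_t_preserves_p(self):
        a = welch_t([1, 2, 3], [2, 4, 6])
        b = welch_t([2, 4, 6], [1, 2, 3])
        assert a.t == pytest.approx(-b.t)
        assert a.p_value == pytest.approx(b.p_value)

    def test_constant_equal_groups_return_t0_p1(self):
        res = welch_t([5.0, 5.0], [5.0, 5.0])
        assert res.t == 0.0 and res.p_value == 1.0

    def test_constant_unequal_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([5.0, 5.0], [6.0, 6.0])
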