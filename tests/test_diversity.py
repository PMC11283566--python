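import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, hypergeom
from skbio.stats.distance import DistanceMatrix

from rhizoactive import (
    CountTable,
    bray_curtis,
    pairwise_permanova,
    pcoa,
    permanova,
    permdisp,
    resampled_richness,
)


def euclid_dm(x: np.ndarray) -> DistanceMatrix:
    ids = [f"s{i}" for i in range(x.shape[0])]
    return DistanceMatrix(squareform(pdist(np.atleast_2d(x.T).T)), ids=ids)


class TestBrayCurtis:
    def test_disjoint_samples_distance_one(self):
        dm = bray_curtis(pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"]))
        assert dm["a", "b"] == pytest.approx(1.0)

    def test_identical_samples_distance_zero(self):
        dm = bray_curtis(pd.DataFrame([[3, 4], [3, 4]], index=["a", "b"]))
        assert dm["a", "b"] == pytest.approx(0.0)

    def test_formula_value(self):
        dm = bray_curtis(pd.DataFrame([[6, 2], [2, 2]], index=["a", "b"]))
        assert dm["a", "b"] == pytest.approx(1 - 8 / 12)

    def test_all_zero_pair_defined_as_zero_with_warning(self):
        warn = []
        dm = bray_curtis(
            pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=["a", "b", "c"]), warn=warn)
        assert dm["a", "b"] == 0.0
        assert warn

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[1, -1], [0, 1]], index=["a", "b"]))

    def test_counts_vs_relative_abundance_agree_for_equal_row_sums(self):
        counts = pd.DataFrame([[6, 2, 2], [2, 2, 6]], index=["a", "b"])
        rel = counts.div(counts.sum(axis=1), axis=0)
        assert bray_curtis(counts)["a", "b"] == pytest.approx(
            bray_curtis(rel)["a", "b"])


class TestPCoA:
    def test_equilateral_geometry(self):
        dm = DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert pos == pytest.approx([0.5, 0.5])
        sides = pdist(res.coordinates.to_numpy())
        assert sides == pytest.approx([1.0, 1.0, 1.0])

    def test_euclidean_distances_recovered_exactly(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        res = pcoa(dm)
        assert np.allclose(pdist(res.coordinates.to_numpy()), pdist(pts), atol=1e-9)
        assert res.negative_eigenvalue_mass == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_samples_coincide(self):
        x = pd.DataFrame([[5, 1], [5, 1], [1, 5]], index=list("abc"))
        res = pcoa(bray_curtis(x))
        coords = res.coordinates
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_matches_skbio_eigenvalues(self, rng):
        x = pd.DataFrame(rng.poisson(10, size=(5, 8)),
                         index=[f"s{i}" for i in range(5)])
        dm = bray_curtis(x)
        mine = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(dm, method="eigh")
        assert np.allclose(
            sorted(mine.eigenvalues), sorted(theirs.eigvals), atol=1e-9)


class TestPermanova:
    def test_univariate_equals_classical_anova_f(self):
        dm = euclid_dm(np.array([[0.0], [1.0], [10.0], [11.0]]))
        meta = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=dm.ids)
        res = permanova(dm, meta, ["g"], n_perm=99, seed=0)
        assert res[0].pseudo_F == pytest.approx(200.0, abs=1e-9)

    def test_matches_anova_on_random_balanced_designs(self, rng):
        for _ in range(5):
            y = rng.normal(size=9)
            dm = euclid_dm(y.reshape(-1, 1))
            labels = np.repeat(["A", "B", "C"], 3)
            meta = pd.DataFrame({"g": labels}, index=dm.ids)
            res = permanova(dm, meta, ["g"], n_perm=9, seed=0)
            f_ref = f_oneway(*(y[labels == lv] for lv in "ABC")).statistic
            assert res[0].pseudo_F == pytest.approx(f_ref, abs=1e-9)

    def test_matches_skbio_one_way_statistic(self, rng):
        x = pd.DataFrame(rng.poisson(20, size=(10, 6)),
                         index=[f"s{i}" for i in range(10)])
        dm = bray_curtis(x)
        meta = pd.DataFrame({"g": ["A"] * 5 + ["B"] * 5}, index=dm.ids)
        mine = permanova(dm, meta, ["g"], n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(dm, meta["g"].values, permutations=0)
        assert mine[0].pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_r2_components_sum_to_one(self, rng):
        x = pd.DataFrame(rng.poisson(20, size=(12, 6)),
                         index=[f"s{i}" for i in range(12)])
        dm = bray_curtis(x)
        meta = pd.DataFrame({
            "a": list("pq") * 6, "b": ["u"] * 6 + ["v"] * 6}, index=dm.ids)
        res = permanova(dm, meta, ["a", "b", "a:b"], n_perm=9, seed=0)
        assert sum(r.R2 for r in res) == pytest.approx(1.0, abs=1e-12)

    def test_confounded_terms_raise(self):
        dm = euclid_dm(np.arange(4.0).reshape(-1, 1))
        meta = pd.DataFrame({"a": list("xxyy"), "b": list("xxyy")}, index=dm.ids)
        with pytest.raises(ValueError, match="aliased"):
            permanova(dm, meta, ["a", "b"], n_perm=9)

    def test_exact_enumeration_matches_brute_force(self, rng):
        from itertools import permutations as all_perms

        y = rng.normal(size=6)
        dm = euclid_dm(y.reshape(-1, 1))
        labels = np.array(["A"] * 3 + ["B"] * 3)
        meta = pd.DataFrame({"g": labels}, index=dm.ids)
        res = permanova(dm, meta, ["g"], permutations="exact")
        f_obs = f_oneway(y[:3], y[3:]).statistic
        hits = sum(
            f_oneway(np.array(p)[:3], np.array(p)[3:]).statistic >= f_obs - 1e-12
            for p in all_perms(y)
        )
        assert res[0].p_value == pytest.approx(hits / 720)


class TestPairwisePermanova:
    def test_three_levels_give_three_pairs(self, rng):
        x = pd.DataFrame(rng.poisson(15, size=(12, 5)),
                         index=[f"s{i}" for i in range(12)])
        dm = bray_curtis(x)
        meta = pd.DataFrame({"g": ["A"] * 4 + ["B"] * 4 + ["C"] * 4}, index=dm.ids)
        out = pairwise_permanova(dm, meta, "g", n_perm=49, seed=0)
        assert len(out) == 3
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_small_level_skipped_with_warning(self, rng):
        x = pd.DataFrame(rng.poisson(15, size=(5, 4)),
                         index=[f"s{i}" for i in range(5)])
        dm = bray_curtis(x)
        meta = pd.DataFrame({"g": ["A", "A", "B", "B", "C"]}, index=dm.ids)
        warn = []
        out = pairwise_permanova(dm, meta, "g", n_perm=49, seed=0, warn=warn)
        assert len(out) == 1
        assert len(warn) == 2


class TestPermdisp:
    def test_mirrored_clouds_have_equal_dispersion(self, rng):
        pts = rng.normal(size=(8, 2))
        cloud = np.vstack([pts, pts + 50.0])
        dm = DistanceMatrix(squareform(pdist(cloud)),
                            ids=[str(i) for i in range(16)])
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=dm.ids)
        res = permdisp(dm, groups, n_perm=99, seed=0)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"], rel=1e-6)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_power_against_unequal_spread(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.vstack([rng.normal(0, 1, size=(10, 2)),
                           rng.normal(0, 5, size=(10, 2))])
            dm = DistanceMatrix(squareform(pdist(x)),
                                ids=[str(i) for i in range(20)])
            groups = pd.Series(["tight"] * 10 + ["wide"] * 10, index=dm.ids)
            res = permdisp(dm, groups, n_perm=199, seed=seed)
            hits += res.p_value < 0.05
        assert hits >= 9

    def test_centroid_mode_matches_hand_computation_1d(self, rng):
        y = rng.normal(size=10)
        dm = euclid_dm(y.reshape(-1, 1))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.ids)
        res = permdisp(dm, groups, n_perm=49, seed=0, center="centroid")
        hand = np.concatenate([np.abs(y[:5] - y[:5].mean()),
                               np.abs(y[5:] - y[5:].mean())])
        assert np.allclose(np.sort(res.distances.to_numpy()), np.sort(hand))

    def test_matches_skbio_centroid_statistic(self, rng):
        x = pd.DataFrame(rng.poisson(25, size=(12, 6)),
                         index=[f"s{i}" for i in range(12)])
        dm = bray_curtis(x)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.ids)
        res = permdisp(dm, groups, n_perm=9, seed=0, center="centroid")
        ref = skbio.stats.distance.permdisp(
            dm, groups.values, test="centroid", permutations=9)
        assert res.F == pytest.approx(ref["test statistic"], rel=1e-6)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(12, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([3.0, -7.0])
        groups = pd.Series(["a"] * 6 + ["b"] * 6,
                           index=[str(i) for i in range(12)])
        f1 = permdisp(DistanceMatrix(squareform(pdist(pts)), ids=groups.index),
                      groups, n_perm=9, seed=0).F
        f2 = permdisp(DistanceMatrix(squareform(pdist(moved)), ids=groups.index),
                      groups, n_perm=9, seed=0).F
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_singleton_group_raises(self):
        dm = euclid_dm(np.arange(3.0).reshape(-1, 1))
        groups = pd.Series(["a", "a", "b"], index=dm.ids)
        with pytest.raises(ValueError):
            permdisp(dm, groups)


class TestResampledRichness:
    def test_full_depth_counts_all_taxa(self):
        table = CountTable(pd.DataFrame([[10, 10, 10]], index=["s"],
                                        columns=["a", "b", "c"]))
        rich = resampled_richness(table, 30, n_resamples=5, seed=0)
        assert rich["s"] == pytest.approx(3.0)

    def test_rare_taxon_matches_hypergeometric_expectation(self):
        table = CountTable(pd.DataFrame([[1000, 1]], index=["s"],
                                        columns=["common", "rare"]))
        rich = resampled_richness(table, 10, n_resamples=400, seed=1)
        expected = 1 + hypergeom(1001, 1, 10).sf(0)
        assert 1.0 < rich["s"] < 2.0
        assert rich["s"] == pytest.approx(expected, abs=0.02)

    def test_depth_above_min_total_raises(self, toy_counts):
        with pytest.raises(ValueError):
            resampled_richness(toy_counts, 1000)
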