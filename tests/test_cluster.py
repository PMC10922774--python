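import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from larvascreen import (
    cluster_profiles,
    elbow_k,
    hclust,
    kmeans,
    overlap_report,
    pca2,
    reference_cluster,
    simulate_profile_matrix,
    standardize,
)
from larvascreen.metrics import BEHAVIOR_NAMES
from larvascreen.profiling import DegenerateInputError, ProfileMatrix

B = list(BEHAVIOR_NAMES)


def naive_complete_linkage_heights(X):
    """O(n^3) reference agglomeration: merge the closest pair of clusters
    under the max-pairwise-distance rule, recording merge heights."""
    X = np.asarray(X, float)
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i, j in itertools.combinations(range(len(clusters)), 2):
            h = max(d[a, b] for a in clusters[i] for b in clusters[j])
            if h < best[0]:
                best = (h, (i, j))
        h, (i, j) = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


def brute_force_kmeans_inertia(X, k=2):
    """Exhaustive minimum of within-cluster sum of squares over all
    2-partitions."""
    X = np.asarray(X, float)
    n = len(X)
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        bits = [(mask >> i) & 1 for i in range(n)]
        groups = [X[[i for i in range(n) if bits[i] == g]] for g in (0, 1)]
        if any(len(g) == 0 for g in groups):
            continue
        ss = sum(((g - g.mean(axis=0)) ** 2).sum() for g in groups)
        best = min(best, ss)
    return best


class TestPCA2:
    def test_planar_data_fully_explained(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 25))
        coefs = rng.normal(size=(40, 2))
        X = pd.DataFrame(coefs @ basis, columns=B,
                         index=[f"C{i}" for i in range(40)])
        emb = pca2(X)
        assert emb.explained_variance.sum() == pytest.approx(1.0)
        assert emb.explained_variance[0] >= emb.explained_variance[1]

    def test_isotropic_cloud_spreads_variance(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(5000, 25)), columns=B)
        emb = pca2(X)
        # each of the top components should carry roughly 1/25 of variance
        for ev in emb.explained_variance:
            assert ev == pytest.approx(1 / 25, rel=0.2)

    def test_duplicating_rows_preserves_loadings(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(20, 25)), columns=B)
        e1 = pca2(X)
        e2 = pca2(pd.concat([X, X], ignore_index=True))
        np.testing.assert_allclose(e1.loadings, e2.loadings, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(15, 25)), columns=B)
        emb = pca2(X)
        for comp in emb.loadings:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_rank_deficient_rejected(self):
        X = pd.DataFrame(np.ones((5, 25)), columns=B)
        with pytest.raises(DegenerateInputError):
            pca2(X)


class TestKMeans:
    def test_two_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal([-10, 0], 1.0, (20, 2))
        b = rng.normal([10, 0], 1.0, (20, 2))
        X = pd.DataFrame(np.vstack([a, b]))
        asg = kmeans(X, k=2, seed=0)
        labels = asg.labels.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_k1_inertia_is_total_ss(self):
        rng = np.random.default_rng(1)
        X = np.asarray(rng.normal(size=(30, 2)))
        asg = kmeans(pd.DataFrame(X), k=1, seed=0)
        assert asg.inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_partition_minimum(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 2))
        asg = kmeans(pd.DataFrame(X), k=2, seed=0, n_init=50)
        assert asg.inertia == pytest.approx(brute_force_kmeans_inertia(X), rel=1e-9)

    def test_inertia_non_increasing_in_k(self):
        pm, _, _ = simulate_profile_matrix(n_compounds=80, n_reference_like=20, seed=4)
        emb = pca2(standardize(pm))
        inertias = [kmeans(emb.coords, k, seed=0).inertia for k in range(1, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans(pd.DataFrame(np.eye(3)), k=4)


class TestElbow:
    def test_four_separated_blobs_give_k4(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        X = np.vstack([rng.normal(c, 1.0, (40, 2)) for c in centers])
        res = elbow_k(pd.DataFrame(X), k_max=8, seed=2)
        assert res.k == 4
        assert not res.low_curvature

    def test_single_blob_flags_low_curvature(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 2)))
        res = elbow_k(X, k_max=8, seed=3)
        assert res.low_curvature

    def test_inertia_at_k_equals_n_is_zero(self):
        X = pd.DataFrame(np.arange(10.0).reshape(5, 2))
        assert kmeans(X, k=5, seed=0).inertia == pytest.approx(0.0, abs=1e-12)

    def test_narrow_range_rejected(self):
        with pytest.raises(ValueError):
            elbow_k(pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2))), k_max=2)


class TestHclust:
    def test_three_collinear_points_hand_trace(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 3.0]}, index=["a", "b", "c"])
        dend = hclust(X)
        np.testing.assert_allclose(dend.heights, [1.0, 3.0])

    def test_duplicate_rows_merge_at_zero(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=list("abc"))
        dend = hclust(X)
        assert dend.heights[0] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_heights_match_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 4))
        dend = hclust(pd.DataFrame(X))
        np.testing.assert_allclose(
            np.sort(dend.heights), np.sort(naive_complete_linkage_heights(X)),
            atol=1e-9,
        )

    def test_heights_monotone(self):
        rng = np.random.default_rng(9)
        dend = hclust(pd.DataFrame(rng.normal(size=(30, 5))))
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_non_finite_rejected(self):
        X = pd.DataFrame([[1.0, np.nan], [0.0, 0.0]])
        with pytest.raises(ValueError):
            hclust(X)

    def test_newick_export_parses(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 3)),
                         index=[f"M1A{i}" for i in range(1, 7)])
        nwk = hclust(X).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 6


class TestReferenceCluster:
    def test_singleton_when_cut_at_n(self):
        X = pd.DataFrame(
            np.vstack([np.zeros((4, 2)) + np.arange(4)[:, None], [100.0, 100.0]]),
            index=list("abcde"),
        )
        dend = hclust(X)
        assert reference_cluster(dend, "e", k=5) == set()

    def test_planted_archetype_set_recovered_by_both_rules(self):
        pm, truth, ref = simulate_profile_matrix(
            n_compounds=150, n_reference_like=20, seed=5
        )
        sm = standardize(pm)
        emb = pca2(sm)
        km = kmeans(emb.coords, k=4, seed=5)
        planted = set(truth.index[truth == "csa_like"]) - {ref}
        km_set = reference_cluster(km, ref)
        hc_set = reference_cluster(hclust(sm), ref, k=4)
        assert km_set == planted
        assert hc_set == planted

    def test_missing_reference_raises(self):
        pm, _, _ = simulate_profile_matrix(n_compounds=20, n_reference_like=5, seed=0)
        km = kmeans(standardize(pm).for_clustering(), k=2, seed=0)
        with pytest.raises(KeyError):
            reference_cluster(km, "NOT_THERE")


class TestOverlapReport:
    def _pm(self, n=10, seed=0):
        pm, _, ref = simulate_profile_matrix(n_compounds=n, n_reference_like=4, seed=seed)
        return pm, ref

    def test_identical_sets(self):
        pm, ref = self._pm()
        s = set(pm.compounds[1:4])
        rep = overlap_report(s, s, pm, pm.compounds[0])
        assert rep.intersection == s and rep.union == s

    def test_disjoint_sets(self):
        pm, ref = self._pm()
        a, b = set(pm.compounds[1:4]), set(pm.compounds[4:8])
        rep = overlap_report(a, b, pm, pm.compounds[0])
        assert len(rep.union) == 7 and len(rep.intersection) == 0

    def test_duplicate_row_correlates_perfectly(self):
        pm, ref = self._pm()
        vals = pm.values.copy()
        vals.loc["DUP"] = vals.loc[ref]
        pm2 = ProfileMatrix(vals)
        rep = overlap_report({"DUP"}, {"DUP"}, pm2, ref)
        assert rep.r_to_reference["DUP"] == pytest.approx(1.0)
        assert rep.mean_pairwise_r_kmeans == pytest.approx(1.0)

    def test_empty_sets_no_crash(self):
        pm, ref = self._pm()
        rep = overlap_report(set(), set(), pm, pm.compounds[0])
        assert rep.union == set()
        assert np.isnan(rep.mean_r_to_reference_kmeans)


class TestPipeline:
    def test_deterministic_given_seed(self):
        pm, _, ref = simulate_profile_matrix(n_compounds=100, n_reference_like=12, seed=8)
        r1 = cluster_profiles(pm, ref, seed=8).report.to_dict()
        r2 = cluster_profiles(pm, ref, seed=8).report.to_dict()
        assert r1 == r2

    def test_option_sweep_covers_grid(self):
        from larvascreen import sweep_cluster_options

        pm, truth, ref = simulate_profile_matrix(n_compounds=100, n_reference_like=12, seed=9)
        grid = sweep_cluster_options(pm, ref, seed=9, k=4)
        assert len(grid) == 4
        assert set(grid["standardize"]) == {True, False}
        assert set(grid["correlation_definition"]) == {"pairwise", "to_reference"}
        planted = int((truth == "csa_like").sum()) - 1
        assert (grid["n_kmeans"] == planted).any()
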