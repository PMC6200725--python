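"""Clustering, neighbor-joining lineage and cosine subset assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from eealineage import (
    UpregulationProfile,
    build_lineage,
    early_burst_genes,
    earliest_cluster,
    enumerate_subsets,
    gene_cluster_profiles,
    hierarchical_clusters,
    neighbor_joining,
    pairwise_distance,
    subset_assignment,
)
from .conftest import random_additive_matrix


def _profile(mat):
    mat = np.asarray(mat, dtype=int)
    return UpregulationProfile(
        matrix=pd.DataFrame(
            mat,
            index=[f"g{i}" for i in range(mat.shape[0])],
            columns=[f"p{j}" for j in range(mat.shape[1])],
        ),
        threshold=1.0,
    )


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        prof = _profile([[1, 0], [1, 0]])  # p0=(1,1), p1=(0,0)
        d = pairwise_distance(prof)
        assert d.loc["p0", "p1"] == pytest.approx(np.sqrt(2))
        prof2 = _profile([[1, 1], [1, 1]])
        assert pairwise_distance(prof2).loc["p0", "p1"] == 0.0

    def test_four_gene_difference_is_two(self):
        mat = np.zeros((6, 2), dtype=int)
        mat[:4, 0] = 1
        d = pairwise_distance(_profile(mat))
        assert d.loc["p0", "p1"] == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 2, size=(15, 10))
        d = pairwise_distance(_profile(mat))
        for a in range(10):
            for b in range(10):
                ref = np.sqrt(((mat[:, a] - mat[:, b]) ** 2).sum())
                assert d.iloc[a, b] == pytest.approx(ref)


class TestHierarchicalClusters:
    def test_two_separated_blocks_recovered(self):
        mat = np.zeros((20, 10), dtype=int)
        mat[:10, :5] = 1
        mat[10:, 5:] = 1
        cs = hierarchical_clusters(_profile(mat), k=2)
        left = set(cs.labels.iloc[:5])
        right = set(cs.labels.iloc[5:])
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_planted_four_clusters_recovered(self):
        rng = np.random.default_rng(1)
        truth = np.repeat(np.arange(4), 15)
        mat = np.zeros((80, 60), dtype=int)
        for c in range(4):
            block = slice(c * 20, (c + 1) * 20)
            mat[block][:, truth == c] = (rng.random((20, 15)) < 0.9).astype(int)
        cs = hierarchical_clusters(_profile(mat), k=4)
        labels = [int(l[1:]) for l in cs.labels]
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 2, size=(10, 5))
        cs = hierarchical_clusters(_profile(mat), k=5)
        assert cs.labels.nunique() == 5

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_clusters(_profile(np.eye(3, dtype=int)), k=7)

    def test_mean_profiles_match_labels(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 2, size=(25, 12))
        prof = _profile(mat)
        cs = hierarchical_clusters(prof, k=3)
        for c in cs.mean_profiles.columns:
            members = cs.members(c)
            ref = prof.matrix[members].mean(axis=1)
            pd.testing.assert_series_equal(cs.mean_profiles[c], ref, check_names=False)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = pd.DataFrame([[0.0, 3.5], [3.5, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree, clamped = neighbor_joining(d)
        assert tree.find("a").distance(tree.find("b")) == pytest.approx(3.5)
        assert clamped == []

    def test_three_taxa_closed_form(self):
        # d(a,b)=3, d(a,c)=5, d(b,c)=6  ->  la=1, lb=2, lc=4
        d = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree, _ = neighbor_joining(d)
        for x, y in itertools.combinations("abc", 2):
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(d.loc[x, y])

    def test_additive_matrices_reconstructed(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            dist = random_additive_matrix(rng, n)
            tree, _ = neighbor_joining(dist)
            for a, b in itertools.combinations(dist.index, 2):
                got = tree.find(a).distance(tree.find(b))
                assert got == pytest.approx(dist.loc[a, b], abs=1e-9)

    def test_matches_skbio_nj_topology(self):
        """Independent oracle: scikit-bio's NJ yields the same path lengths."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        dist = random_additive_matrix(rng, 6)
        mine, _ = neighbor_joining(dist)
        ref = skbio_nj(DistanceMatrix(dist.to_numpy(), ids=list(dist.index)))
        for a, b in itertools.combinations(dist.index, 2):
            assert mine.find(a).distance(mine.find(b)) == pytest.approx(
                ref.find(a).distance(ref.find(b)), abs=1e-9
            )

    def test_duplicate_taxa_join_at_zero(self):
        means = pd.DataFrame(
            {"C1": [1.0, 0.0], "C2": [1.0, 0.0], "C3": [0.0, 1.0]}
        )
        lt = build_lineage(means)
        assert lt.path_length("C1", "C2") == pytest.approx(0.0, abs=1e-12)


class TestLineage:
    def test_newick_contains_normal_leaf(self):
        means = pd.DataFrame({"C1": [0.9, 0.1], "C2": [0.1, 0.9]})
        lt = build_lineage(means)
        nwk = lt.newick()
        assert "normal" in nwk and nwk.endswith(";")
        assert set(lt.taxa) == {"C1", "C2", "normal"}

    def test_earliest_cluster_nearest_to_normal(self):
        means = pd.DataFrame(
            {"C1": [0.2, 0.0, 0.0], "C2": [0.9, 0.9, 0.0], "C3": [0.9, 0.9, 0.9]}
        )
        lt = build_lineage(means)
        assert earliest_cluster(lt) == "C1"

    def test_earliest_matches_brute_force_paths(self):
        rng = np.random.default_rng(6)
        means = pd.DataFrame(rng.random((12, 4)), columns=["C1", "C2", "C3", "C4"])
        lt = build_lineage(means)
        dists = {c: lt.path_length("normal", c) for c in ["C1", "C2", "C3", "C4"]}
        assert earliest_cluster(lt) == min(dists, key=dists.get)

    def test_tie_breaks_to_smallest_label(self):
        means = pd.DataFrame({"C1": [0.5, 0.0], "C2": [0.0, 0.5]})
        lt = build_lineage(means)
        assert earliest_cluster(lt) in ("C1", "C2")
        if lt.path_length("normal", "C1") == lt.path_length("normal", "C2"):
            assert earliest_cluster(lt) == "C1"


class TestSubsets:
    def test_fifteen_subsets_for_four_clusters(self):
        subs = enumerate_subsets(4)
        assert len(subs) == 15
        assert subs[0] == (0, 0, 0, 1)
        assert subs[-1] == (1, 1, 1, 1)

    def test_k1_and_k3(self):
        assert enumerate_subsets(1) == [(1,)]
        subs = enumerate_subsets(3)
        assert len(subs) == 7
        assert subs[0] == (0, 0, 1) and subs[-1] == (1, 1, 1)

    def test_all_ones_profile_assigned_full_subset(self):
        prof = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g0"],
                            columns=["C1", "C2", "C3", "C4"])
        sa = subset_assignment(prof)
        assert sa.table.loc["g0", "subset"] == "1111"
        assert sa.table.loc["g0", "similarity"] == pytest.approx(1.0)

    def test_three_cluster_profile(self):
        prof = pd.DataFrame([[0.1, 0.9, 0.9, 0.9]], index=["g0"],
                            columns=["C1", "C2", "C3", "C4"])
        sa = subset_assignment(prof)
        assert sa.table.loc["g0", "subset"] == "0111"

    def test_zero_profile_unassigned(self):
        prof = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], index=["g0"],
                            columns=["C1", "C2", "C3", "C4"])
        sa = subset_assignment(prof)
        assert bool(sa.table.loc["g0", "unassigned"])

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(7)
        P = rng.random((300, 4))
        prof = pd.DataFrame(P, index=[f"g{i}" for i in range(300)],
                            columns=["C1", "C2", "C3", "C4"])
        sa = subset_assignment(prof)
        subsets = enumerate_subsets(4)
        for gi in range(300):
            best, best_sim, best_key = None, -1.0, None
            for si, v in enumerate(subsets):
                va = np.array(v, dtype=float)
                sim = P[gi] @ va / (np.linalg.norm(P[gi]) * np.linalg.norm(va))
                key = (-sim, sum(v), si)
                if best_key is None or key < best_key:
                    best, best_sim, best_key = v, sim, key
            assert sa.table.iloc[gi]["subset"] == "".join(map(str, best))
            assert sa.table.iloc[gi]["similarity"] == pytest.approx(best_sim)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        P = rng.random((50, 4))
        prof1 = pd.DataFrame(P, columns=list("ABCD"))
        prof2 = pd.DataFrame(P * 7.3, columns=list("ABCD"))
        a = subset_assignment(prof1).table["subset"]
        b = subset_assignment(prof2).table["subset"]
        assert (a == b).all()


class TestEarlyBurst:
    def _assignments(self):
        prof = pd.DataFrame(
            [[0.95, 0.9, 0.9, 0.9],   # all clusters -> early burst
             [0.0, 0.9, 0.9, 0.0],    # excludes C1
             [0.9, 0.05, 0.0, 0.0]],  # C1 only
            index=["gAll", "gMid", "gC1"],
            columns=["C1", "C2", "C3", "C4"],
        )
        return subset_assignment(prof)

    def test_inclusive_tier_requires_earliest_position(self):
        tiers = early_burst_genes(self._assignments(), earliest="C1")
        assert tiers["inclusive"] == {"gAll", "gC1"}
        assert tiers["strict"] == {"gC1"}

    def test_eea_restriction(self):
        tiers = early_burst_genes(self._assignments(), earliest="C1",
                                  eea_set={"gAll"})
        assert tiers["inclusive"] == {"gAll"}

    def test_gene_profiles_consistent_with_members(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 2, size=(30, 16))
        prof = _profile(mat)
        cs = hierarchical_clusters(prof, k=4)
        gp = gene_cluster_profiles(prof, cs)
        for c in gp.columns:
            members = cs.members(c)
            np.testing.assert_allclose(
                gp[c].to_numpy(), prof.matrix[members].mean(axis=1).to_numpy()
            )
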