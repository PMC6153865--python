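"""CLUSTER / SIMPROF / ANOSIM / SIMPER against oracles and the fixture."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from lander.errors import ValidationError
from lander.obsdata import CommunityMatrix
from lander.resemblance import ResemblanceMatrix, bray_curtis, transform_abundance
from lander.community_tests import (
    anosim,
    cluster_group_average,
    simper,
    simprof,
    simprof_cluster,
)


def _cm(values, transform="sqrt"):
    values = np.asarray(values, dtype=float)
    ids = [f"s{i}" for i in range(values.shape[0])]
    taxa = [f"t{j}" for j in range(values.shape[1])]
    return CommunityMatrix(pd.DataFrame(values, index=ids, columns=taxa), transform=transform)


def _random_resemblance(rng, n):
    s = rng.uniform(5, 95, size=(n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 100.0)
    return ResemblanceMatrix([f"s{i}" for i in range(n)], s)


class TestCluster:
    def test_two_samples_merge_at_their_similarity(self):
        r = ResemblanceMatrix(["a", "b"], np.array([[100.0, 37.0], [37.0, 100.0]]))
        dendro = cluster_group_average(r)
        assert dendro.root.height == pytest.approx(37.0)
        assert set(dendro.root.members) == {"a", "b"}

    def test_fixture_first_split_is_the_depth_divide(self, study_resemblance):
        dendro = cluster_group_average(study_resemblance)
        sides = {frozenset(c.members) for c in dendro.root.children}
        assert sides == {frozenset({"1", "2", "3"}), frozenset({"4", "5", "6", "7", "8"})}

    def test_against_scipy_upgma_oracle(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 7):
            for _ in range(10):
                r = _random_resemblance(rng, n)
                dendro = cluster_group_average(r)
                heights = sorted(
                    node.height for node in dendro.nodes() if not node.is_leaf
                )
                z = linkage(squareform(r.dissimilarities(), checks=False), method="average")
                scipy_heights = sorted(100.0 - z[:, 2])
                assert np.allclose(heights, scipy_heights)

    def test_monotone_fusion_levels_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            dendro = cluster_group_average(_random_resemblance(rng, 6))
            for node in dendro.nodes():
                for child in node.children:
                    assert child.height >= node.height - 1e-9

    def test_leaves_are_all_samples_once(self, study_resemblance):
        dendro = cluster_group_average(study_resemblance)
        leaves = [n.members[0] for n in dendro.nodes() if n.is_leaf]
        assert sorted(leaves) == sorted(study_resemblance.sample_ids)

    def test_newick_round_trips_through_dendropy(self, study_resemblance):
        import dendropy

        nwk = cluster_group_average(study_resemblance).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == sorted(
            study_resemblance.sample_ids
        )

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            ResemblanceMatrix(["a", "b"], np.array([[100.0, 10.0], [20.0, 100.0]]))


class TestSimprof:
    def test_two_samples_untestable(self):
        res = simprof(_cm([[1, 2], [2, 1]]), seed=0)
        assert not res.testable and res.p is None and not res.significant

    def test_deterministic_under_seed(self, sqrt_matrix):
        a = simprof(sqrt_matrix, n_perm_mean=50, n_perm_test=49, seed=42)
        b = simprof(sqrt_matrix, n_perm_mean=50, n_perm_test=49, seed=42)
        assert a.pi == b.pi and a.p == b.p

    def test_p_respects_permutation_floor(self, sqrt_matrix):
        res = simprof(sqrt_matrix, n_perm_mean=100, n_perm_test=99, seed=3)
        assert res.p >= 1 / (99 + 1)

    def test_fixture_recursion_finds_the_two_depth_groups(self, sqrt_matrix):
        sc = simprof_cluster(sqrt_matrix, seed=7)
        assert sorted(tuple(sorted(g)) for g in sc.groups) == [
            ("1", "2", "3"),
            ("4", "5", "6", "7", "8"),
        ]
        assert sc.dendrogram.root.simprof.significant


class TestAnosim:
    def test_fixture_complete_separation(self, study_resemblance, depth_grouping):
        res = anosim(study_resemblance, depth_grouping, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.exact and res.n_permutations_used == 56
        assert res.p == pytest.approx(1 / 56)

    def test_exact_p_independent_of_seed(self, study_resemblance, depth_grouping):
        p_values = {anosim(study_resemblance, depth_grouping, seed=s).p for s in (0, 1, 99)}
        assert len(p_values) == 1

    def test_complete_separation_gives_r_one(self):
        # all between dissimilarities strictly exceed all within
        s = np.array(
            [
                [100.0, 90.0, 10.0, 12.0],
                [90.0, 100.0, 11.0, 13.0],
                [10.0, 11.0, 100.0, 85.0],
                [12.0, 13.0, 85.0, 100.0],
            ]
        )
        r = ResemblanceMatrix(list("abcd"), s)
        assert anosim(r, ["g1", "g1", "g2", "g2"], seed=0).R == pytest.approx(1.0)

    def test_single_group_rejected(self, study_resemblance):
        with pytest.raises(ValidationError):
            anosim(study_resemblance, ["g"] * 8)

    def test_r_statistic_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.integers(1, 10, size=(7, 5)).astype(float)
            r = bray_curtis(_cm(x, transform="none"))
            labels = ["a", "a", "a", "b", "b", "b", "b"]
            ours = anosim(r, labels, seed=0)
            dm = skbio_distance.DistanceMatrix(r.dissimilarities() / 100.0, ids=r.sample_ids)
            theirs = skbio_distance.anosim(dm, np.array(labels), permutations=99)
            assert ours.R == pytest.approx(float(theirs["test statistic"]), abs=1e-12)

    def test_monte_carlo_path(self, study_resemblance, depth_grouping):
        res = anosim(study_resemblance, depth_grouping, max_permutations=10, n_monte_carlo=999, seed=5)
        assert not res.exact
        assert res.p >= 1 / 1000
        assert res.R == pytest.approx(1.0)


class TestSimper:
    def test_fixture_average_transformed_abundances(self, sqrt_matrix, depth_grouping):
        table = simper(sqrt_matrix, depth_grouping)
        shallow = table.groups["shallow"].table.set_index("species")
        deep = table.groups["deep"].table.set_index("species")
        assert shallow.loc["Centrophorus granulosus", "avg_abundance"] == pytest.approx(
            (1 + np.sqrt(2) + np.sqrt(3)) / 3
        )
        assert deep.loc["Lepidion lepidion", "avg_abundance"] == pytest.approx(
            (1 + np.sqrt(2)) / 5
        )

    def test_decomposition_sums_to_pair_similarity(self, sqrt_matrix, depth_grouping):
        from lander.community_tests import pair_species_shares

        x = sqrt_matrix.values
        s = bray_curtis(sqrt_matrix).similarities
        ids = sqrt_matrix.sample_ids
        for j in range(len(ids)):
            for k in range(j + 1, len(ids)):
                if depth_grouping[ids[j]] == depth_grouping[ids[k]]:
                    assert pair_species_shares(x[j], x[k]).sum() == pytest.approx(
                        s[j, k], abs=1e-9
                    )

    def test_group_average_equals_mean_within_similarity(self, sqrt_matrix, depth_grouping):
        table = simper(sqrt_matrix, depth_grouping)
        s = bray_curtis(sqrt_matrix).similarities
        ids = sqrt_matrix.sample_ids
        for label, g in table.groups.items():
            idx = [i for i, sid in enumerate(ids) if depth_grouping[sid] == label]
            sims = [s[a, b] for i, a in enumerate(idx) for b in idx[i + 1:]]
            assert g.average_similarity == pytest.approx(np.mean(sims), abs=1e-9)

    def test_identical_samples_group(self):
        m = _cm([[4.0, 1.0], [4.0, 1.0], [9.0, 0.0]], transform="none")
        with pytest.warns(UserWarning):  # g2 singleton -> skipped
            table = simper(m, ["g1", "g1", "g2"])
        g = table.groups["g1"]
        assert g.average_similarity == pytest.approx(100.0)
        assert g.table["pct_contribution"].sum() == pytest.approx(100.0)

    def test_singleton_group_warns_and_skips(self, sqrt_matrix):
        labels = ["solo"] + ["rest"] * 7
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = simper(sqrt_matrix, labels)
        assert "solo" not in table.groups
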