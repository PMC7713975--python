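"""PCA, admixture EM, p-distances, NJ trees, bootstrap and Newick IO."""

import numpy as np
import pytest
from skbio import DistanceMatrix

import popsweep as ps
from popsweep.structure import (tree_bipartitions, tree_from_newick_string)

import oracles


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, 100)
        G = np.vstack([row, row, rng.integers(0, 3, 100)])
        coords, _ = ps.pca_patterson(G, n_components=2)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-6)

    def test_eigenvalues_non_increasing_and_non_negative(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(20, 500))
        _, eigvals = ps.pca_patterson(G)
        assert (np.diff(eigvals) <= 1e-9).all()
        assert (eigvals >= 0).all()

    def test_coordinates_invariant_to_sample_order_up_to_sign(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, size=(15, 300))
        perm = rng.permutation(15)
        c1, _ = ps.pca_patterson(G, 3)
        c2, _ = ps.pca_patterson(G[perm], 3)
        for k in range(3):
            direct = np.allclose(c1[perm, k], c2[:, k], atol=1e-8)
            flipped = np.allclose(c1[perm, k], -c2[:, k], atol=1e-8)
            assert direct or flipped

    def test_three_populations_separate_on_leading_pcs(self):
        cohort = ps.simulate_balding_nichols(ps.BaldingNicholsSpec(
            n_pops=3, F_per_pop=(0.15,) * 3, n_diploids_per_pop=30,
            n_sites=5_000, seed=4))
        coords, _ = ps.pca_patterson(cohort.dosage, 2)
        from sklearn.cluster import KMeans
        labels = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(coords)
        true = np.repeat(np.arange(3), 30)
        purity = sum(np.bincount(true[labels == c]).max()
                     for c in range(3)) / len(true)
        assert purity == 1.0

    def test_no_polymorphic_sites_rejected(self):
        with pytest.raises(ValueError):
            ps.pca_patterson(np.zeros((5, 10)))

    def test_tracy_widom_flags_real_structure(self):
        cohort = ps.simulate_balding_nichols(ps.BaldingNicholsSpec(
            n_pops=2, F_per_pop=(0.3, 0.3), n_diploids_per_pop=30,
            n_sites=2_000, seed=5))
        _, eigvals = ps.pca_patterson(cohort.dosage)
        tw = ps.tracy_widom_scores(eigvals, n_samples=60)
        assert tw.sig_05[0]  # the structure axis is significant


class TestAdmixture:
    def test_k1_closed_form_binomial_loglik(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(10, 200))
        fit = ps.admixture_em(G, K=1, seed=0, n_restarts=1, max_iter=50)
        np.testing.assert_allclose(fit.Q, 1.0)
        freq = G.mean(axis=0) / 2.0
        np.testing.assert_allclose(fit.F[0], np.clip(freq, 1e-9, 1 - 1e-9),
                                   atol=1e-6)
        f = np.clip(freq, 1e-9, 1 - 1e-9)
        expected = (G * np.log(f) + (2 - G) * np.log(1 - f)).sum()
        assert fit.loglik == pytest.approx(expected, rel=1e-9)

    def test_loglik_monotone_every_iteration(self):
        cohort = ps.simulate_balding_nichols(ps.BaldingNicholsSpec(
            n_pops=2, F_per_pop=(0.2, 0.2), n_diploids_per_pop=15,
            n_sites=500, seed=6))
        fit = ps.admixture_em(cohort.dosage, K=2, seed=1, n_restarts=2,
                              max_iter=200)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_unadmixed_ground_truth_recovered(self):
        cohort = ps.simulate_balding_nichols(ps.BaldingNicholsSpec(
            n_pops=2, F_per_pop=(0.2, 0.2), n_diploids_per_pop=20,
            n_sites=1_000, seed=7))
        fit = ps.admixture_em(cohort.dosage, K=2, seed=2, n_restarts=3,
                              max_iter=300)
        truth = np.zeros((40, 2))
        truth[:20, 0] = 1.0
        truth[20:, 1] = 1.0
        Q = ps.align_q_columns(fit.Q, truth)
        rmse = np.sqrt(np.mean((Q - truth) ** 2))
        assert rmse < 0.05

    def test_q_rows_simplex_and_f_bounded(self):
        rng = np.random.default_rng(8)
        G = rng.integers(0, 3, size=(12, 100))
        G[rng.random(G.shape) < 0.1] = -1  # missing genotypes excluded
        fit = ps.admixture_em(G, K=3, seed=0, n_restarts=1, max_iter=60)
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert (fit.Q >= 0).all()
        assert ((fit.F >= 0) & (fit.F <= 1)).all()

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            ps.admixture_em(np.zeros((3, 10)), K=4)


class TestPDistance:
    def test_identical_and_opposite_samples(self):
        G = np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        D = ps.p_distance_matrix(G, ["a", "b", "c"])
        assert D["a", "b"] == 0.0
        G2 = np.array([[0, 0, 2, 2], [2, 2, 0, 0]])
        D2 = ps.p_distance_matrix(G2, ["x", "y"])
        assert D2["x", "y"] == 1.0

    def test_matches_double_loop_oracle_with_missingness(self):
        rng = np.random.default_rng(11)
        G = rng.integers(0, 3, size=(8, 200)).astype(float)
        G[rng.random(G.shape) < 0.15] = -1
        D = ps.p_distance_matrix(G, [f"s{i}" for i in range(8)])
        expected = oracles.p_distance_double_loop(G)
        np.testing.assert_allclose(D.data, expected, atol=1e-12)

    def test_no_shared_sites_rejected(self):
        G = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError, match="shared"):
            ps.p_distance_matrix(G, ["a", "b"])


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> exact distances
        D = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ["A", "B", "C", "D"])
        tree = ps.nj_tree(D)
        assert tree_bipartitions(tree) == {frozenset({"A", "B"})}
        for a, b in [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
                     ("B", "D"), ("C", "D")]:
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                D[a, b], abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_topology_and_path_lengths_on_random_additive_matrices(self, n_taxa):
        """NJ consistency: exact recovery on additive matrices (random trees)."""
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(5):
            D, labels, edges = oracles.random_additive_tree(rng, n_taxa)
            tree = ps.nj_tree(DistanceMatrix(D, labels))
            assert tree_bipartitions(tree) == oracles.tree_splits_from_edges(
                edges, n_taxa)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        assert tree.find(a).distance(tree.find(b)) == \
                            pytest.approx(D[i, j], abs=1e-9)

    def test_star_matrix_accepted_with_exact_path_lengths(self):
        D = DistanceMatrix((np.ones((4, 4)) - np.eye(4)) * 2, list("abcd"))
        tree = ps.nj_tree(D)
        for a in "abcd":
            for b in "abcd":
                if a < b:
                    assert tree.find(a).distance(tree.find(b)) == \
                        pytest.approx(2.0, abs=1e-9)

    def test_tip_set_preserved(self):
        rng = np.random.default_rng(1)
        D, labels, _ = oracles.random_additive_tree(rng, 6)
        tree = ps.nj_tree(DistanceMatrix(D, labels))
        assert {t.name for t in tree.tips()} == set(labels)


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, size=(6, 100))
        _, support = ps.bootstrap_support(G, [f"s{i}" for i in range(6)],
                                          n_reps=1, seed=0)
        assert set(support.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(8, 200))
        labels = [f"s{i}" for i in range(8)]
        _, s1 = ps.bootstrap_support(G, labels, n_reps=50, seed=42)
        _, s2 = ps.bootstrap_support(G, labels, n_reps=50, seed=42)
        assert s1 == s2

    def test_clear_two_cluster_split_gets_high_support(self):
        cohort = ps.simulate_balding_nichols(ps.BaldingNicholsSpec(
            n_pops=2, F_per_pop=(0.3, 0.3), n_diploids_per_pop=8,
            n_sites=800, seed=9))
        tree, support = ps.bootstrap_support(cohort.dosage, cohort.samples,
                                             n_reps=100, seed=1)
        pop1 = frozenset(s for s, p in zip(cohort.samples, cohort.sample_pops)
                         if p == "pop1")
        split_support = [v for bp, v in support.items()
                         if bp == pop1 or bp == frozenset(cohort.samples) - pop1]
        assert split_support and split_support[0] >= 95.0


class TestNewickIO:
    def test_round_trip_topology_lengths_supports(self, tmp_path):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, size=(6, 150))
        labels = [f"s{i}" for i in range(6)]
        tree, support = ps.bootstrap_support(G, labels, n_reps=20, seed=3)
        path = tmp_path / "t.nwk"
        ps.write_newick(tree, path)
        back = ps.read_newick(path)
        assert tree_bipartitions(back) == tree_bipartitions(tree)
        for a in labels:
            for b in labels:
                if a < b:
                    assert back.find(a).distance(back.find(b)) == pytest.approx(
                        tree.find(a).distance(tree.find(b)), abs=1e-9)
        sups = {getattr(n, "support", None) for n in back.non_tips()}
        assert any(s is not None for s in sups)

    def test_outgroup_rooting_places_outgroup_as_sister(self):
        tree = tree_from_newick_string("((A:1,B:2):1,(C:3,D:4):1,OUT:2);")
        rooted = ps.root_with_outgroup(tree, "OUT")
        children = rooted.children
        assert len(children) == 2
        names = [{t.name for t in c.tips()} if not c.is_tip() else {c.name}
                 for c in children]
        assert {"OUT"} in names
        other = names[0] if names[1] == {"OUT"} else names[1]
        assert other == {"A", "B", "C", "D"}

    def test_malformed_newick_raises(self, tmp_path):
        bad = tmp_path / "bad.nwk"
        bad.write_text("((A:1,B:2;")
        with pytest.raises(ValueError):
            ps.read_newick(bad)
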