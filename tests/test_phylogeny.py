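"""Distance phylogeny: NJ exactness on additive matrices, OLS branch
lengths against an independent design-matrix solve, CNI against exhaustive
topology enumeration, bootstrap determinism."""

import itertools

import dendropy
import numpy as np
import pytest

import snpatlas as sa
from snpatlas import phylogeny as ph
from snpatlas.align import msa_from_rows

from conftest import ISOLATES


def random_binary_tree(rng, taxa):
    """Random unrooted binary topology with random positive branch lengths."""
    topologies = None
    tree = ph.Tree(list(taxa))
    center = tree.new_node()
    order = list(rng.permutation(len(taxa)))
    for leaf in order[:3]:
        tree.link(int(leaf), center, float(rng.uniform(0.05, 1.0)))
    for leaf in order[3:]:
        u, v = tree.edges()[int(rng.integers(0, len(tree.edges())))]
        mid = tree.new_node()
        length = tree.adj[u][v]
        tree.unlink(u, v)
        tree.link(u, mid, length / 2)
        tree.link(mid, v, length / 2)
        tree.link(int(leaf), mid, float(rng.uniform(0.05, 1.0)))
    return tree


class TestDistanceMatrix:
    def test_identical_rows_zero_distance(self):
        rows = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTAAAA"}
        msa = msa_from_rows(rows, "a")
        D = sa.p_distance_matrix(msa, ["a", "b", "c"])
        assert D.get("a", "b") == 0.0

    def test_quarter_distance(self):
        rows = {"a": "AAAA", "b": "AAAT", "c": "TTTT"}
        msa = msa_from_rows(rows, "a")
        D = sa.p_distance_matrix(msa, ["a", "b", "c"])
        assert D.get("a", "b") == 0.25

    def test_pairwise_deletion_ignores_gaps_and_ambiguities(self):
        rows = {"a": "ACGT-CR", "b": "ACTTACA", "c": "ACGTACA"}
        msa = msa_from_rows(rows, "a")
        D = sa.p_distance_matrix(msa, ["a", "b", "c"])
        # a vs b: comparable columns 0,1,2,3,5 (gap col 4, R col 6): 1 diff
        assert D.get("a", "b") == pytest.approx(1 / 5)

    def test_validation(self):
        with pytest.raises(ValueError):
            ph.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            ph.DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_distances_track_generating_tree(self, small_sim, small_msa):
        """p-distances rank-correlate with generating-tree path lengths."""
        from scipy.stats import spearmanr

        _, _, _, newick = small_sim
        D = sa.p_distance_matrix(small_msa, ISOLATES)
        gen = dendropy.Tree.get(data=newick, schema="newick")
        pdm = gen.phylogenetic_distance_matrix()
        taxon = {t.label: t for t in gen.taxon_namespace}
        true_d, est_d = [], []
        for a, b in itertools.combinations(ISOLATES, 2):
            true_d.append(pdm.patristic_distance(taxon[a], taxon[b]))
            est_d.append(D.get(a, b))
        rho = spearmanr(true_d, est_d).statistic
        assert rho > 0.9


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        values = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        D = ph.DistanceMatrix(["A", "B", "C"], values)
        tree = ph.neighbor_joining(D)
        # star tree: pendant lengths from the closed form
        a = 0.5 * (0.3 + 0.5 - 0.6)
        b = 0.5 * (0.3 + 0.6 - 0.5)
        c = 0.5 * (0.5 + 0.6 - 0.3)
        center = 3
        assert tree.adj[0][center] == pytest.approx(a)
        assert tree.adj[1][center] == pytest.approx(b)
        assert tree.adj[2][center] == pytest.approx(c)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n_taxa):
        """100 random additive matrices across sizes: NJ returns the
        generating topology and branch lengths."""
        reps = {4: 30, 5: 25, 6: 20, 7: 15, 8: 10}[n_taxa]
        for rep in range(reps):
            rng = np.random.default_rng(1000 * n_taxa + rep)
            taxa = [f"t{i}" for i in range(n_taxa)]
            true_tree = random_binary_tree(rng, taxa)
            D = true_tree.leaf_path_lengths()
            nj = ph.neighbor_joining(D)
            assert nj.splits() == true_tree.splits()
            # branch lengths: compare leaf path length matrices
            np.testing.assert_allclose(
                nj.leaf_path_lengths().values, D.values, atol=1e-9
            )

    def test_identical_rows_join_first(self):
        values = np.array(
            [
                [0.0, 0.0, 0.4, 0.4],
                [0.0, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.2],
                [0.4, 0.4, 0.2, 0.0],
            ]
        )
        D = ph.DistanceMatrix(["a", "b", "c", "d"], values)
        tree = ph.neighbor_joining(D)
        # a and b are cherries; the single internal split separates {c, d}
        assert tree.splits() == {frozenset({"c", "d"})}

    def test_matches_dendropy_on_random_matrices(self):
        """Independent cross-check: same topology as dendropy's NJ."""
        for rep in range(10):
            rng = np.random.default_rng(3000 + rep)
            n = 6
            taxa = [f"t{i}" for i in range(n)]
            noise = rng.uniform(0.01, 1.0, size=(n, n))
            values = (noise + noise.T) / 2
            np.fill_diagonal(values, 0.0)
            D = ph.DistanceMatrix(taxa, values)
            ours = ph.neighbor_joining(D)

            csv = "," + ",".join(taxa) + "\n" + "\n".join(
                taxa[i] + "," + ",".join(str(values[i][j]) for j in range(n))
                for i in range(n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=__import__("io").StringIO(csv)
            )
            theirs = pdm.nj_tree()
            their_splits = set()
            all_taxa = frozenset(taxa)
            anchor = min(taxa)
            for node in theirs.preorder_internal_node_iter():
                labels = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(labels) < n:
                    side = labels if anchor not in labels else all_taxa - labels
                    if 1 < len(side) < n - 1:
                        their_splits.add(side)
            assert ours.splits() == their_splits


class TestOlsTreeLength:
    def test_additive_exact_recovery(self):
        rng = np.random.default_rng(42)
        taxa = [f"t{i}" for i in range(5)]
        true_tree = random_binary_tree(rng, taxa)
        D = true_tree.leaf_path_lengths()
        topo = true_tree.copy()
        branch, total = ph.ols_tree_length(topo, D)
        expected_total = sum(
            length for u, nbrs in true_tree.adj.items()
            for v, length in nbrs.items() if u < v
        )
        assert total == pytest.approx(expected_total)
        fitted = topo.leaf_path_lengths()
        np.testing.assert_allclose(fitted.values, D.values, atol=1e-9)

    def test_three_taxon_closed_form(self):
        values = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        D = ph.DistanceMatrix(["A", "B", "C"], values)
        tree = ph.neighbor_joining(D)
        _, total = ph.ols_tree_length(tree, D)
        assert total == pytest.approx(0.5 * (0.3 + 0.5 + 0.6))

    def test_matches_networkx_design_solve(self):
        """Brute-force oracle: build the pair-path design matrix with
        networkx and solve by least squares independently."""
        import networkx as nx

        for rep in range(10):
            rng = np.random.default_rng(700 + rep)
            taxa = [f"t{i}" for i in range(5)]
            tree = random_binary_tree(rng, taxa)
            noise = rng.uniform(0.05, 1.0, size=(5, 5))
            values = (noise + noise.T) / 2
            np.fill_diagonal(values, 0.0)
            D = ph.DistanceMatrix(taxa, values)
            _, total = ph.ols_tree_length(tree.copy(), D)

            graph = nx.Graph()
            for u, nbrs in tree.adj.items():
                for v in nbrs:
                    graph.add_edge(u, v)
            edges = sorted(tuple(sorted(e)) for e in graph.edges)
            edge_idx = {e: k for k, e in enumerate(edges)}
            pairs = list(itertools.combinations(range(5), 2))
            A = np.zeros((len(pairs), len(edges)))
            d = np.zeros(len(pairs))
            for row, (i, j) in enumerate(pairs):
                path = nx.shortest_path(graph, i, j)
                for u, v in zip(path, path[1:]):
                    A[row, edge_idx[tuple(sorted((u, v)))]] = 1
                d[row] = values[i, j]
            expected, *_ = np.linalg.lstsq(A, d, rcond=None)
            assert total == pytest.approx(float(expected.sum()))


class TestMinimumEvolutionSearch:
    def test_true_tree_is_fixed_point(self):
        rng = np.random.default_rng(9)
        taxa = [f"t{i}" for i in range(5)]
        true_tree = random_binary_tree(rng, taxa)
        D = true_tree.leaf_path_lengths()
        result = ph.me_search_cni(true_tree.copy(), D)
        assert result.splits() == true_tree.splits()

    def test_equals_exhaustive_minimum_100_random_matrices(self):
        """CNI hill climb from NJ reaches the global ME optimum over all 15
        unrooted 5-taxon topologies, for 100 random matrices."""
        for rep in range(100):
            rng = np.random.default_rng(5000 + rep)
            taxa = [f"t{i}" for i in range(5)]
            noise = rng.uniform(0.05, 1.0, size=(5, 5))
            values = (noise + noise.T) / 2
            np.fill_diagonal(values, 0.0)
            D = ph.DistanceMatrix(taxa, values)
            start = ph.neighbor_joining(D)
            result = ph.me_search_cni(start, D)
            _, result_len = ph.ols_tree_length(result, D)
            _, best_len = ph.exhaustive_me(D)
            assert result_len == pytest.approx(best_len, abs=1e-10)

    def test_result_never_worse_than_start(self):
        rng = np.random.default_rng(77)
        taxa = [f"t{i}" for i in range(6)]
        noise = rng.uniform(0.05, 1.0, size=(6, 6))
        values = (noise + noise.T) / 2
        np.fill_diagonal(values, 0.0)
        D = ph.DistanceMatrix(taxa, values)
        start = random_binary_tree(rng, taxa)
        _, start_len = ph.ols_tree_length(start.copy(), D)
        result = ph.me_search_cni(start, D)
        _, result_len = ph.ols_tree_length(result, D)
        assert result_len <= start_len + 1e-12

    def test_enumerate_topologies_count(self):
        assert len(ph.enumerate_topologies(list("abcde"))) == 15
        keys = {t.canonical_key() for t in ph.enumerate_topologies(list("abcde"))}
        assert len(keys) == 15


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, small_msa):
        result = ph.bootstrap_support(small_msa, ISOLATES, n_reps=1, seed=3)
        assert set(result.supports.values()) <= {0.0, 100.0}

    def test_deterministic_given_seed(self, small_msa):
        a = ph.bootstrap_support(small_msa, ISOLATES, n_reps=20, seed=5)
        b = ph.bootstrap_support(small_msa, ISOLATES, n_reps=20, seed=5)
        assert a.supports == b.supports

    def test_strong_signal_saturates_supports(self, small_msa):
        """Hundreds of clean synapomorphies per branch: every true split
        at 100%."""
        result = ph.bootstrap_support(small_msa, ISOLATES, n_reps=100, seed=7)
        assert result.supports
        assert all(v == 100.0 for v in result.supports.values())
        # and the point tree is the generating ladder
        assert result.tree.splits() == {
            frozenset({"M", "I12"}),
            frozenset({"S", "I07"}),  # complement of {M, I12, E2}
        }

    def test_supports_invariant_under_taxon_permutation(self, small_msa):
        a = ph.bootstrap_support(small_msa, ISOLATES, n_reps=20, seed=5)
        b = ph.bootstrap_support(
            small_msa, list(reversed(ISOLATES)), n_reps=20, seed=5
        )
        assert a.supports == b.supports

    def test_invalid_reps(self, small_msa):
        with pytest.raises(ValueError):
            ph.bootstrap_support(small_msa, ISOLATES, n_reps=0, seed=1)


class TestNewick:
    def test_outgroup_rooted_newick_parses(self, small_msa):
        result = ph.bootstrap_support(small_msa, ISOLATES, n_reps=10, seed=2)
        text = result.tree.newick(supports=result.supports, outgroup="I07")
        tree = dendropy.Tree.get(data=text, schema="newick")
        children = tree.seed_node.child_nodes()
        assert len(children) == 2
        sides = [
            {l.taxon.label for l in child.leaf_iter()} for child in children
        ]
        assert {"I07"} in sides

    def test_negative_lengths_clamped_in_output(self):
        tree = ph.Tree(["a", "b", "c"])
        center = tree.new_node()
        tree.link(0, center, 0.1)
        tree.link(1, center, -0.05)
        tree.link(2, center, 0.2)
        text = tree.newick()
        assert "-0.05" not in text
        assert "b:0" in text
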