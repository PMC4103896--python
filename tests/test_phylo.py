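import itertools

import dendropy
import numpy as np
import pytest

from helpers import (
    brute_force_midpoint_height,
    exhaustive_parsimony,
    five_leaf_topologies,
    max_root_leaf_distance,
    topology_lstsq_residual,
)
from pptriad.align import MultipleAlignment
from pptriad.phylo import (
    DistanceMatrix,
    PhyloError,
    bootstrap_support,
    distance_matrix,
    fitch_changes,
    is_monophyletic,
    leaf_bipartitions,
    midpoint_root,
    nj_tree,
    read_newick,
    same_topology,
    write_newick,
)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def _additive_matrix(tree):
    """Path-length distances of a dendropy tree as (labels, ndarray)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        t1 = tree.taxon_namespace.get_taxon(labels[i])
        t2 = tree.taxon_namespace.get_taxon(labels[j])
        d[i, j] = d[j, i] = pdm.distance(t1, t2)
    return labels, d


def _random_tree(rng, n):
    """Random binary tree with exponential branch lengths."""
    taxa = [f"t{i}" for i in range(n)]
    nodes = []
    tns = dendropy.TaxonNamespace(taxa)
    for lab in taxa:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        node.edge.length = float(rng.exponential(1.0)) + 0.05
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(1.0)) + 0.05
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for x in nodes:
        root.add_child(x)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        msa = MultipleAlignment(ids=list("abc"), rows=["AAAA"] * 3)
        dm = distance_matrix(msa, "p_distance")
        assert np.all(dm.d == 0)

    def test_closed_forms(self):
        msa = MultipleAlignment(ids=list("abc"), rows=["AAAA", "AATT", "AAAA"])
        dm_p = distance_matrix(msa, "p_distance")
        i, j = dm_p.labels.index("a"), dm_p.labels.index("b")
        assert dm_p.d[i, j] == pytest.approx(0.5)
        dm_pois = distance_matrix(msa, "poisson")
        assert dm_pois.d[i, j] == pytest.approx(-np.log(0.5))

    def test_pairwise_deletion_skips_gap_columns(self):
        msa = MultipleAlignment(ids=list("abc"), rows=["AA-A", "AATA", "AAAA"])
        dm = distance_matrix(msa, "p_distance")
        i, j = dm.labels.index("a"), dm.labels.index("b")
        assert dm.d[i, j] == 0.0  # the mismatching column is gapped in a

    def test_matches_direct_recount(self, default_family):
        from pptriad.align import star_msa

        _, records, _, _ = default_family
        msa = star_msa(records[:6], records[0].id)
        dm = distance_matrix(msa, "p_distance")
        for i, j in itertools.combinations(range(6), 2):
            ra, rb = msa.rows[i], msa.rows[j]
            diffs = comp = 0
            for x, y in zip(ra, rb):
                if x != "-" and y != "-":
                    comp += 1
                    diffs += x != y
            assert dm.d[i, j] == pytest.approx(diffs / comp)

    def test_no_overlap_pair_errors(self):
        msa = MultipleAlignment(ids=list("abc"), rows=["AA--", "--TT", "AATT"])
        with pytest.raises(PhyloError, match="degenerate"):
            distance_matrix(msa, "p_distance")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(list("abc"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0),
                           "c": pytest.approx(3.0)}

    def test_five_taxon_additive_recovery_and_path_lengths(self):
        src = _tree("((a:1,b:2):1,(c:1,d:3):2,e:4);")
        labels, d = _additive_matrix(src)
        out = nj_tree(DistanceMatrix(labels, d))
        assert same_topology(out, src)
        _, d_out = _additive_matrix(out)
        assert np.allclose(d_out, d, atol=1e-9)

    def test_nj_topology_beats_all_15_by_least_squares(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            src = _random_tree(rng, 5)
            labels, d = _additive_matrix(src)
            out = nj_tree(DistanceMatrix(labels, d))
            out_bips = leaf_bipartitions(out)
            best = None
            for topo in five_leaf_topologies(labels):
                resid = topology_lstsq_residual(topo, labels, d)
                if best is None or resid < best[0]:
                    best = (resid, topo)
            (p1, p2, _e) = best[1]
            # winning topology's two cherries must be bipartitions of the NJ tree
            all_leaves = frozenset(labels)
            ref = min(labels)
            for pair in (p1, p2):
                side = frozenset(pair)
                canon = side if ref not in side else all_leaves - side
                assert canon in out_bips

    def test_noise_robustness_six_taxa(self):
        rng = np.random.default_rng(9)
        src = _random_tree(rng, 6)
        labels, d = _additive_matrix(src)
        noisy = d * (1 + rng.uniform(-0.01, 0.01, size=d.shape))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        assert same_topology(
            nj_tree(DistanceMatrix(labels, d)),
            nj_tree(DistanceMatrix(labels, noisy)),
        )

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        for _ in range(5):
            src = _random_tree(rng, 8)
            labels, d = _additive_matrix(src)
            ours = nj_tree(DistanceMatrix(labels, d))
            theirs = skbio_nj(SkbioDM(d, ids=labels))
            their_bips = set()
            all_leaves = frozenset(labels)
            ref = min(labels)
            for node in theirs.non_tips():
                below = frozenset(t.name for t in node.tips())
                side = below if ref not in below else all_leaves - below
                if 1 < len(side) < len(labels) - 1:
                    their_bips.add(side)
            assert leaf_bipartitions(ours) == their_bips

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(3)
        src = _random_tree(rng, 6)
        labels, d = _additive_matrix(src)
        perm = list(rng.permutation(len(labels)))
        labels_p = [labels[i] for i in perm]
        d_p = d[np.ix_(perm, perm)]
        assert same_topology(
            nj_tree(DistanceMatrix(labels, d)),
            nj_tree(DistanceMatrix(labels_p, d_p)),
        )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhyloError):
            DistanceMatrix(list("abc"), np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


class TestBootstrap:
    def _split_msa(self):
        return MultipleAlignment(
            ids=["p1", "p2", "q1", "q2"],
            rows=["AAAACCCC", "AAAACCCC", "TTTTCCCC", "TTTTCCCC"],
        )

    def test_forced_split_support_100(self):
        tree = bootstrap_support(self._split_msa(), n_reps=50, seed=1, model="p_distance")
        supports = [n.label for n in tree.preorder_node_iter()
                    if n.label is not None and not n.is_leaf()]
        assert supports == ["100"]

    def test_same_seed_identical_supports(self, default_family):
        from pptriad.align import star_msa

        _, records, _, _ = default_family
        msa = star_msa(records[:8], records[0].id)
        t1 = bootstrap_support(msa, n_reps=30, seed=42)
        t2 = bootstrap_support(msa, n_reps=30, seed=42)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_within_sampling_error_across_seeds(self, default_family):
        from pptriad.align import star_msa

        _, records, _, _ = default_family
        msa = star_msa(records[:8], records[0].id)

        def support_map(tree):
            out = {}
            for node in tree.preorder_node_iter():
                if node.is_leaf() or node is tree.seed_node or node.label is None:
                    continue
                below = frozenset(l.taxon.label for l in node.leaf_iter())
                out[below] = float(node.label)
            return out

        s1 = support_map(bootstrap_support(msa, n_reps=200, seed=1))
        s2 = support_map(bootstrap_support(msa, n_reps=200, seed=2))
        assert s1.keys() == s2.keys()
        for k in s1:
            assert abs(s1[k] - s2[k]) <= 12  # ~3 binomial SD at n=200

    def test_column_duplication_preserves_topology(self):
        msa = self._split_msa()
        doubled = MultipleAlignment(ids=msa.ids, rows=[r + r for r in msa.rows])
        t1 = nj_tree(distance_matrix(msa, "p_distance"))
        t2 = nj_tree(distance_matrix(doubled, "p_distance"))
        assert same_topology(t1, t2)

    def test_supports_in_range(self, default_family):
        from pptriad.align import star_msa

        _, records, _, _ = default_family
        msa = star_msa(records[:8], records[0].id)
        tree = bootstrap_support(msa, n_reps=25, seed=0)
        for node in tree.preorder_node_iter():
            if node.label is not None and not node.is_leaf():
                assert 0.0 <= float(node.label) <= 100.0


class TestMidpointRoot:
    def test_two_leaf_tree(self):
        tree = _tree("(a:1,b:3);")
        rooted = midpoint_root(tree)
        dists = sorted(
            sum((n.edge.length or 0) for n in leaf.ancestor_iter(inclusive=True)
                if n.parent_node is not None or n is leaf)
            for leaf in rooted.leaf_node_iter()
        )
        assert max_root_leaf_distance(rooted) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            src = _random_tree(rng, 10)
            rooted = midpoint_root(src)
            assert max_root_leaf_distance(rooted) == pytest.approx(
                brute_force_midpoint_height(src), abs=1e-9
            )

    def test_input_not_mutated(self):
        src = _tree("((a:1,b:2):1,(c:1,d:3):2,e:4);")
        before = src.as_string(schema="newick")
        midpoint_root(src)
        assert src.as_string(schema="newick") == before


class TestMonophyly:
    def test_singleton_and_full_set(self):
        tree = _tree("((a:1,b:2):1,(c:1,d:3):2,e:4);")
        assert is_monophyletic(tree, {"a"})
        assert is_monophyletic(tree, {"a", "b", "c", "d", "e"})

    def test_planted_clade_true_and_swap_false(self, clean_family):
        _, records, _, truth = clean_family
        animals = {r.id for r in records if r.id.startswith("animal")}
        assert is_monophyletic(truth.tree, animals, root_first=False)
        other = next(r.id for r in records if r.id.startswith("fungi"))
        swapped = (animals - {next(iter(animals))}) | {other}
        assert not is_monophyletic(truth.tree, swapped, root_first=False)

    def test_unknown_leaf_errors(self):
        tree = _tree("((a:1,b:2):1,(c:1,d:3):2,e:4);")
        with pytest.raises(PhyloError):
            is_monophyletic(tree, {"zz"})


class TestFitch:
    def test_uniform_states_zero_changes(self):
        tree = _tree("((a:1,b:2):1,(c:1,d:3):2,e:4);")
        assert fitch_changes(tree, {l: "M" for l in "abcde"}) == 0

    def test_two_leaf_tree_one_change(self):
        tree = _tree("(a:1,b:1);")
        assert fitch_changes(tree, {"a": "M", "b": "V"}) == 1

    def test_missing_state_errors(self):
        tree = _tree("(a:1,b:1);")
        with pytest.raises(PhyloError):
            fitch_changes(tree, {"a": "M"})

    def test_matches_exhaustive_minimisation(self):
        rng = np.random.default_rng(12)
        states = "MVAE"
        for _ in range(8):
            tree = _random_tree(rng, 6)
            chars = {f"t{i}": states[int(rng.integers(4))] for i in range(6)}
            assert fitch_changes(tree, chars) == exhaustive_parsimony(tree, chars)

    def test_bounds(self, clean_family):
        _, records, _, truth = clean_family
        chars = {l: truth.leaf_motif[l]["residues"][1] for l in truth.leaf_motif}
        n = len(chars)
        changes = fitch_changes(truth.tree, chars)
        assert 0 <= changes <= n - 1


class TestNewickIO:
    def test_roundtrip_topology_lengths_supports(self, tmp_path):
        msa = MultipleAlignment(
            ids=["p1", "p2", "q1", "q2"],
            rows=["AAAACCCC", "AAAACCCC", "TTTTCCCC", "TTTTCCCC"],
        )
        tree = bootstrap_support(msa, n_reps=20, seed=0, model="p_distance")
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        assert same_topology(tree, back)
        orig = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        new = {l.taxon.label: l.edge.length for l in back.leaf_node_iter()}
        for k in orig:
            assert new[k] == pytest.approx(orig[k], abs=1e-6)
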