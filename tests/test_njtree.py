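"""Neighbor joining, monophyly testing, and bootstrap support."""

import numpy as np
import pytest

import _oracles
from barcodekit.align import Alignment
from barcodekit.distance import DistanceMatrix
from barcodekit.njtree import (
    bootstrap_support,
    consensus_tree,
    nj,
    species_resolution_tree,
)


def dm_of(ids, values):
    return DistanceMatrix(ids=list(ids), values=np.array(values, float))


class TestNeighborJoining:
    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(dm_of("ab", [[0, 1], [1, 0]]))

    def test_three_taxa_unique_topology(self):
        tree = nj(dm_of("abc", [[0, .2, .4], [.2, 0, .6], [.4, .6, 0]]))
        assert sorted(map(str, tree.leaf_names)) == ["a", "b", "c"]
        assert tree.bipartitions() == []  # star, no internal edge

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)): d(A,B)=3, d(A,C)=5, d(A,D)=3,
        # d(B,C)=6, d(B,D)=4, d(C,D)=4
        dm = dm_of("ABCD", [[0, 3, 5, 3],
                            [3, 0, 6, 4],
                            [5, 6, 0, 4],
                            [3, 4, 4, 0]])
        tree = nj(dm)
        assert frozenset({"A", "B"}) in tree.bipartitions() or \
            frozenset({"C", "D"}) in tree.bipartitions()
        # path lengths reproduce the additive matrix
        newick = tree.to_newick(with_support=False)
        import dendropy

        t = dendropy.Tree.get(data=newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for (i, a), (j, b) in [((0, "A"), (1, "B")), ((0, "A"), (2, "C")),
                               ((1, "B"), (3, "D")), ((2, "C"), (3, "D"))]:
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                dm.values[i, j])

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrices_recover_generating_topology(self, n):
        # brute-force oracle: the generating topology is the unique one
        # with zero least-squares residual
        rng = np.random.default_rng(40 + n)
        for rep in range(10):
            values, true_biparts, leaves = _oracles.random_tree_matrix(n, rng)
            tree = nj(dm_of(leaves, values))
            leafset = frozenset(leaves)
            got = frozenset(_oracles.canonical_side(frozenset(b), leafset)
                            for b in tree.bipartitions())
            assert got == true_biparts
            # cross-check the oracle itself: zero residual on truth
            best = None
            for edges in _oracles.enumerate_topologies(leaves):
                r = _oracles.ols_fit_residual(edges, leaves, values)
                biparts = _oracles.topology_bipartitions(edges, leaves)
                if best is None or r < best[0]:
                    best = (r, biparts)
            assert best[1] == true_biparts

    def test_matches_scikit_bio_topology(self):
        import skbio

        rng = np.random.default_rng(77)
        values, _, leaves = _oracles.random_tree_matrix(7, rng)
        # perturb slightly so the matrix is near- but not exactly additive
        noise = rng.normal(0, 0.005, values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        values = np.abs(values + noise)
        values = (values + values.T) / 2
        ours = nj(dm_of(leaves, values))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(values, ids=leaves))
        want = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(leaves) - 1:
                all_l = frozenset(leaves)
                want.add(min(side, all_l - side,
                             key=lambda s: (len(s), sorted(s))))
        got = set()
        all_l = frozenset(leaves)
        for side in ours.bipartitions():
            got.add(min(side, all_l - side, key=lambda s: (len(s), sorted(s))))
        assert got == want

    def test_missing_entries_imputed_with_warning(self, caplog):
        values = np.array([[0, .1, np.nan, .5],
                           [.1, 0, .4, .5],
                           [np.nan, .4, 0, .2],
                           [.5, .5, .2, 0]])
        with caplog.at_level("WARNING"):
            tree = nj(DistanceMatrix(ids=list("abcd"), values=values))
        assert sorted(map(str, tree.leaf_names)) == list("abcd")
        assert any("imputing" in r.message for r in caplog.records)


class TestMonophyly:
    def random_tree(self, n, seed):
        rng = np.random.default_rng(seed)
        values, _, leaves = _oracles.random_tree_matrix(n, rng)
        return nj(dm_of(leaves, values)), leaves

    @pytest.mark.parametrize("n,seed", [(6, 1), (8, 2), (10, 3), (12, 4)])
    def test_against_dendropy_mrca_oracle(self, n, seed):
        import dendropy

        tree, leaves = self.random_tree(n, seed)
        dt = dendropy.Tree.get(data=tree.to_newick(with_support=False),
                               schema="newick")
        dt.is_rooted = False
        dt.encode_bipartitions()
        rng = np.random.default_rng(seed + 100)
        for _ in range(30):
            k = int(rng.integers(2, n))
            subset = set(rng.choice(leaves, size=k, replace=False))
            # oracle: an unrooted tree has this clade iff the bipartition
            # subset | rest appears among its encoded bipartitions
            taxa = set(dt.taxon_namespace.get_taxa(labels=sorted(subset)))
            mask = dt.taxon_namespace.taxa_bitmask(taxa=taxa)
            present = any(
                b.leafset_bitmask == mask
                or b.leafset_bitmask == dt.seed_node.bipartition.leafset_bitmask ^ mask
                for b in dt.bipartition_encoding
            )
            assert tree.is_monophyletic(subset) == present

    def test_single_leaf_and_full_set_trivially_monophyletic(self):
        tree, leaves = self.random_tree(6, 9)
        assert tree.is_monophyletic({leaves[0]})
        assert tree.is_monophyletic(set(leaves))


class TestBootstrapSupport:
    def separable_alignment(self):
        # two species, maximally distant blocks; every resampled replicate
        # separates them
        rows = ["A" * 30, "A" * 30, "T" * 30, "T" * 30, "G" * 15 + "C" * 15]
        ids = ["x1", "x2", "y1", "y2", "z1"]
        species = {"x1": "G x", "x2": "G x", "y1": "G y", "y2": "G y",
                   "z1": "G z"}
        return Alignment("ITS", ids, rows), species

    def test_distinct_species_get_full_support(self):
        aln, species = self.separable_alignment()
        results = bootstrap_support(aln, species, n_reps=30, seed=0)
        assert {r.species for r in results} == {"G x", "G y"}  # no singleton
        assert all(r.bootstrap_support == 100.0 for r in results)
        assert all(r.resolved for r in results)
        assert species_resolution_tree(results) == 100.0

    def test_interleaved_identical_species_unsupported(self):
        rows = ["A" * 30, "A" * 30, "A" * 30, "A" * 30, "T" * 30]
        species = {"x1": "G x", "y1": "G y", "x2": "G x", "y2": "G y",
                   "z1": "G z"}
        aln = Alignment("ITS", ["x1", "y1", "x2", "y2", "z1"], rows)
        results = bootstrap_support(aln, species, n_reps=30, seed=0)
        # identical sequences across two species: no edge can separate
        # either species deterministically
        assert all(not r.monophyletic_in_original or
                   r.bootstrap_support <= 100 for r in results)
        assert species_resolution_tree(results) < 100.0

    def test_same_seed_reproduces_supports(self):
        aln, species = self.separable_alignment()
        r1 = bootstrap_support(aln, species, n_reps=25, seed=42)
        r2 = bootstrap_support(aln, species, n_reps=25, seed=42)
        assert [x.bootstrap_support for x in r1] == \
            [x.bootstrap_support for x in r2]

    def test_supports_invariant_to_row_order(self):
        aln, species = self.separable_alignment()
        perm = [2, 0, 4, 1, 3]
        aln2 = Alignment("ITS", [aln.ids[i] for i in perm],
                         [aln.rows[i] for i in perm])
        r1 = {x.species: x.bootstrap_support
              for x in bootstrap_support(aln, species, n_reps=25, seed=7)}
        r2 = {x.species: x.bootstrap_support
              for x in bootstrap_support(aln2, species, n_reps=25, seed=7)}
        assert r1 == r2

    def test_support_just_below_cutoff_not_resolved(self):
        from barcodekit.njtree import MonophylyResult

        results = [
            MonophylyResult("a", 2, True, 49.0, resolved=False),
            MonophylyResult("b", 2, True, 50.0, resolved=True),
        ]
        assert species_resolution_tree(results) == 50.0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            species_resolution_tree([])


class TestConsensus:
    def test_strict_consensus_keeps_only_universal_clades(self):
        trees = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            values, _, leaves = _oracles.random_tree_matrix(6, rng)
            trees.append(nj(dm_of(leaves, values)))
        strict = consensus_tree(trees, min_frequency=1.0)
        kept = {frozenset(b) for b in strict.bipartitions()}
        for t in trees:
            t_biparts = set()
            all_l = frozenset(t.leaf_names)
            for side in t.bipartitions():
                t_biparts.add(side)
                t_biparts.add(all_l - side)
            assert kept <= t_biparts

    def test_consensus_of_identical_trees_is_that_tree(self):
        rng = np.random.default_rng(5)
        values, biparts, leaves = _oracles.random_tree_matrix(6, rng)
        tree = nj(dm_of(leaves, values))
        cons = consensus_tree([tree, tree, tree], min_frequency=0.5)
        got = {frozenset(b) for b in cons.bipartitions()}
        all_l = frozenset(leaves)
        canon = lambda s: min(s, all_l - s, key=lambda x: (len(x), sorted(x)))
        assert {canon(b) for b in got} == {canon(b) for b in biparts}
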