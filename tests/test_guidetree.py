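import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from conftest import AA, mutate, random_protein
from phylopipe.guidetree import (
    DistanceMatrix,
    alignment_pdistance,
    collapse_ingroup_paralogs,
    is_monophyletic,
    nj_tree,
    pdistance_matrix,
)
from phylopipe.simulate import random_additive_tree, simulate_paralog_family


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick", unquoted_underscores=True),
        schema="newick", taxon_namespace=tns, preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick", unquoted_underscores=True),
        schema="newick", taxon_namespace=tns, preserve_underscores=True,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


class TestPdistance:
    def test_identical_pair_zero(self, rng):
        seq = random_protein(rng, 50)
        dm = pdistance_matrix([("a", seq), ("b", seq)])
        assert dm.values[0, 1] == 0.0

    def test_matrix_invariants(self, rng):
        records = [(f"s{i}", random_protein(rng, 60)) for i in range(3)]
        dm = pdistance_matrix(records)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_planted_divergence_exact(self, rng):
        base = random_protein(rng, 100)
        partner = list(base)
        for i in rng.choice(100, size=10, replace=False):
            partner[i] = str(rng.choice([c for c in AA if c != partner[i]]))
        dm = pdistance_matrix([("a", base), ("b", "".join(partner))])
        assert dm.values[0, 1] == pytest.approx(0.10)

    def test_zero_overlap_maxes_out(self):
        dm = alignment_pdistance(["a", "b"], ["MK--", "--VL"])
        assert dm.values[0, 1] == 1.0

    def test_symmetric_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestNeighborJoining:
    def test_additive_distances_recover_topology(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 17))
            true_tree, dm = random_additive_tree(n, rng)
            assert rf_distance(true_tree, nj_tree(dm)) == 0

    def test_three_leaves(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float))
        tree = nj_tree(dm)
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c"}

    def test_ultrametric_four_leaf_split(self):
        d = np.array(
            [[0, 0.2, 0.8, 0.8], [0.2, 0, 0.8, 0.8], [0.8, 0.8, 0, 0.2], [0.8, 0.8, 0.2, 0]]
        )
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], d))
        assert is_monophyletic(tree, {"a", "b"})
        assert is_monophyletic(tree, {"c", "d"})

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestCollapse:
    def test_identical_triplet_collapsed_first_iteration(self, rng):
        seq = random_protein(rng, 80)
        records = [(f"Op_me_dupx_{i}", seq) for i in range(3)]
        records += [(f"Pl_gr_ta{i:02d}_{i}", mutate(rng, seq, 0.2)) for i in range(10)]
        kept, removed, iters = collapse_ingroup_paralogs(records)
        dup_kept = [n for n, _ in kept if n.startswith("Op_me_dupx")]
        assert len(dup_kept) == 1
        assert sum(1 for r in removed if r.iteration == 1) >= 2

    def test_planted_duplication_clades_recovered(self, rng):
        dup = {"ta01": 2, "ta03": 3, "ta05": 4, "ta07": 2, "ta09": 2}
        records, truth = simulate_paralog_family(rng, n_taxa=10, dup_clades=dup)
        kept, removed, _ = collapse_ingroup_paralogs(records)
        assert len(removed) == sum(size - 1 for size in dup.values())
        kept_names = {n for n, _ in kept}
        originals = {n for n, _ in records if n.endswith("_p0")}
        assert originals <= kept_names  # no planted ortholog lost

    def test_no_same_taxon_sisters_is_fixpoint(self, rng):
        records, _ = simulate_paralog_family(rng, n_taxa=8, dup_clades={})
        kept, removed, iters = collapse_ingroup_paralogs(records)
        assert kept == records and not removed and iters == 1

    def test_collapse_output_is_fixpoint(self, rng):
        records, _ = simulate_paralog_family(rng, n_taxa=10, dup_clades={"ta02": 3, "ta06": 2})
        kept, _, _ = collapse_ingroup_paralogs(records)
        kept2, removed2, _ = collapse_ingroup_paralogs(kept)
        assert kept2 == kept and not removed2

    def test_never_removes_last_sequence_of_taxon(self, rng):
        records, _ = simulate_paralog_family(rng, n_taxa=10, dup_clades={"ta00": 4})
        kept, _, _ = collapse_ingroup_paralogs(records)
        taxa_in = {n.rsplit("_", 1)[0] for n, _ in records}
        taxa_out = {n.rsplit("_", 1)[0] for n, _ in kept}
        assert taxa_in == taxa_out

    def test_fewer_than_three_records_unchanged(self, rng):
        records = [("Op_me_aaaa_1", "MKV"), ("Op_me_aaaa_2", "MKV")]
        kept, removed, iters = collapse_ingroup_paralogs(records)
        assert kept == records and not removed and iters == 0


class TestMonophyly:
    def test_agrees_with_bipartition_enumeration(self, rng):
        from oracles import tree_adjacency, _reachable

        for _ in range(20):
            n = int(rng.integers(4, 13))
            tree, _ = random_additive_tree(n, rng)
            leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            adjacency, labels = tree_adjacency(tree)
            # oracle: all edge-defined sides
            oracle_sides = set()
            for u in adjacency:
                for v in adjacency[u]:
                    if u >= v:
                        continue
                    side = frozenset(
                        labels[x] for x in _reachable(adjacency, u, v) if x in labels
                    )
                    if side and side != leaves:
                        oracle_sides.add(side)
                        oracle_sides.add(leaves - side)
            sample = [frozenset(s) for s in oracle_sides if 2 <= len(s) < n]
            for s in sample[:10]:
                assert is_monophyletic(tree, s)
            # random non-side subsets should usually not be monophyletic
            labels_list = sorted(leaves)
            for _ in range(5):
                k = int(rng.integers(2, n))
                subset = frozenset(rng.choice(labels_list, size=k, replace=False))
                assert is_monophyletic(tree, subset) == (subset in oracle_sides or len(subset) == n)
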