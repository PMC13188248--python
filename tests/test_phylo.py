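"""Progressive alignment, trimming, distance corrections, NJ consistency
on additive matrices, Robinson-Foulds (vs dendropy), and bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from r2scout import simulate as sim
from r2scout.alignment import DEFAULT_AA, global_align
from r2scout.phylo import (
    Msa,
    align_progressive,
    bipartitions,
    distance_matrix,
    identity_matrix,
    neighbor_joining,
    parse_newick,
    partition_trees,
    rf_distance,
    trim_alignment,
)


class TestAlignProgressive:
    def test_identical_pair_aligns_gap_free(self):
        msa = align_progressive({"a": "MKVLW", "b": "MKVLW"})
        assert msa.rows == ["MKVLW", "MKVLW"]

    def test_ungapping_reproduces_inputs(self):
        seqs = {
            "a": "MKVLWAALLVTFLAGTQA",
            "b": "MKVLWAALLVTFLAG",
            "c": "MKVLWAAQQVTFLAGTQA",
            "d": "MKAALLVTFLAGT",
        }
        msa = align_progressive(seqs)
        for t, r in zip(msa.taxa, msa.rows):
            assert r.replace("-", "") == seqs[t]

    def test_two_sequences_match_pairwise_dp_oracle(self):
        a, b = "MKVLWAALLVTFLAGTQAKV", "MKVLWAGTQAKV"
        msa = align_progressive({"a": a, "b": b})
        oracle = global_align(a, b, DEFAULT_AA)
        assert msa.rows == [oracle.aligned_a, oracle.aligned_b]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            align_progressive([("a", "MKV"), ("a", "MKV")])


class TestTrimAlignment:
    def test_gap_free_is_identity(self):
        msa = Msa(taxa=["a", "b"], rows=["MKV", "MKV"])
        trimmed, dropped = trim_alignment(msa)
        assert trimmed.rows == msa.rows and dropped == []

    def test_all_gap_column_dropped_at_any_threshold(self):
        msa = Msa(taxa=["a", "b"], rows=["M-V", "M-V"])
        trimmed, dropped = trim_alignment(msa, max_gap_fraction=0.99)
        assert trimmed.rows == ["MV", "MV"] and dropped == [1]

    def test_threshold_drops_exactly_the_gappy_column(self):
        msa = Msa(
            taxa=list("abcd"),
            rows=["MAV", "M--", "MA-", "MA-"],  # gap fractions 0, 0.25, 0.75
        )
        trimmed, dropped = trim_alignment(msa, max_gap_fraction=0.5)
        assert dropped == [2]
        assert trimmed.n_columns == 2

    def test_everything_dropped_is_an_error(self):
        msa = Msa(taxa=["a", "b"], rows=["--", "--"])
        with pytest.raises(ValueError):
            trim_alignment(msa, max_gap_fraction=0.5)


class TestDistanceMatrix:
    def test_identical_rows_are_zero_under_all_corrections(self):
        msa = Msa(taxa=["a", "b"], rows=["MKVLW", "MKVLW"])
        for corr in ("p", "poisson", "kimura-protein"):
            assert distance_matrix(msa, corr).loc["a", "b"] == 0.0

    def test_poisson_closed_form(self):
        rows = ["A" * 90 + "C" * 10, "A" * 90 + "D" * 10]  # p = 0.10
        msa = Msa(taxa=["a", "b"], rows=rows)
        d = distance_matrix(msa, "poisson").loc["a", "b"]
        assert abs(d - (-np.log(0.9))) < 1e-6  # 0.1053605...

    def test_kimura_closed_form(self):
        rows = ["A" * 90 + "C" * 10, "A" * 90 + "D" * 10]
        msa = Msa(taxa=["a", "b"], rows=rows)
        d = distance_matrix(msa, "kimura-protein").loc["a", "b"]
        assert abs(d - (-np.log(1 - 0.10 - 0.2 * 0.01))) < 1e-6  # 0.1075983...

    def test_disjoint_gap_patterns_raise_naming_the_pair(self):
        msa = Msa(taxa=["a", "b"], rows=["M--", "--V"])
        with pytest.raises(ValueError, match="a.*b"):
            distance_matrix(msa)


def five_taxon_trees():
    """All 15 unrooted binary topologies on 5 leaves, as edge lists built
    by leaf insertion (the standard unrooted-tree enumeration)."""
    base = [("x0", "a"), ("x0", "b"), ("x0", "c")]
    trees4 = []
    for i in range(len(base)):
        edges = [e for j, e in enumerate(base) if j != i]
        u, v = base[i]
        edges += [(u, "x1"), ("x1", v), ("x1", "d")]
        trees4.append(edges)
    trees5 = []
    for edges in trees4:
        for i in range(len(edges)):
            new = [e for j, e in enumerate(edges) if j != i]
            u, v = edges[i]
            new += [(u, "x2"), ("x2", v), ("x2", "e")]
            trees5.append(new)
    return trees5


def additive_matrix(edges, lengths, taxa):
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in zip(edges, lengths):
        g.add_edge(u, v, weight=w)
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, j in itertools.combinations(taxa, 2):
        d = nx.shortest_path_length(g, i, j, weight="weight")
        D.loc[i, j] = D.loc[j, i] = d
    return D


def true_bipartitions(edges, taxa):
    import networkx as nx

    out = set()
    g = nx.Graph(edges)
    for u, v in edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(t for t in taxa if nx.has_path(h, t, u))
        if 2 <= len(side) <= len(taxa) - 2:
            ref = min(taxa)
            out.add(frozenset(set(taxa) - side) if ref in side else side)
    return out


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # distances from ((a:1,b:2):1,(c:3,d:4))
        taxa = list("abcd")
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=taxa, columns=taxa, dtype=float,
        )
        tree = neighbor_joining(D)
        assert bipartitions(tree) == {frozenset("cd")}
        lengths = {}
        for node in tree.walk():
            if node.is_leaf():
                lengths[node.name] = node.length
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}

    def test_three_taxa_three_point_formulas(self):
        taxa = list("abc")
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=taxa, columns=taxa, dtype=float
        )
        tree = neighbor_joining(D)
        lengths = {n.name: n.length for n in tree.walk() if n.is_leaf()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_consistency_on_all_five_taxon_topologies(self):
        """NJ recovers every labeled 5-taxon topology from its additive
        matrix (RF = 0)."""
        taxa = list("abcde")
        rng = np.random.default_rng(33)
        for edges in five_taxon_trees():
            lengths = rng.uniform(0.5, 3.0, size=len(edges))
            D = additive_matrix(edges, lengths, taxa)
            tree = neighbor_joining(D)
            assert bipartitions(tree) == true_bipartitions(edges, taxa)

    def test_outgroup_rooting_places_outgroup_basal(self):
        taxa = list("abcd")
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=taxa, columns=taxa, dtype=float,
        )
        tree = neighbor_joining(D, outgroup="d")
        assert len(tree.children) == 2
        sides = [set(c.leaves()) for c in tree.children]
        assert {"d"} in sides

    def test_unknown_outgroup_rejected(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            neighbor_joining(D, outgroup="z")

    def test_bootstrap_reproducible_and_confident_on_clean_signal(self):
        nwk = "((a:0.3,b:0.3):0.25,((c:0.3,d:0.3):0.25,(e:0.3,f:0.3):0.25):0.1);"
        root = "".join(np.random.default_rng(3).choice(list(sim.AA20), 600))
        leaves = sim.evolve_on_tree(root, nwk, seed=6)
        msa = Msa(taxa=list(leaves), rows=list(leaves.values()))
        D = distance_matrix(msa)
        boot = {"msa": msa, "B": 100, "seed": 5}
        t1 = neighbor_joining(D, bootstrap=boot)
        t2 = neighbor_joining(D, bootstrap=boot)
        assert t1.to_newick() == t2.to_newick()  # bit-exact for a fixed seed
        supports = [
            n.support for n in t1.walk() if n.support is not None
        ]
        assert supports and all(s >= 95 for s in supports)


class TestRfDistance:
    def test_identical_trees_are_zero(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert rf_distance(t, parse_newick(t.to_newick())) == 0

    def test_distinct_quartets_differ_by_two(self):
        t1 = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_caterpillar_vs_balanced_matches_enumeration(self):
        cat = parse_newick("(a:1,(b:1,(c:1,(d:1,(e:1,f:1):1):1):1):1);")
        bal = parse_newick("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);")
        b1 = bipartitions(cat)
        b2 = bipartitions(bal)
        assert rf_distance(cat, bal) == len(b1 ^ b2)

    def test_matches_dendropy_on_random_trees(self):
        import random

        import dendropy
        from dendropy.calculate import treecompare

        ns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        for s in range(5):
            r = random.Random(s)
            d1 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=8, taxon_namespace=ns, rng=r
            )
            d2 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=8, taxon_namespace=ns, rng=r
            )
            for d in (d1, d2):
                d.is_rooted = False
                d.update_bipartitions()
            expected = treecompare.symmetric_difference(d1, d2)
            mine = rf_distance(
                parse_newick(d1.as_string(schema="newick")),
                parse_newick(d2.as_string(schema="newick")),
            )
            assert mine == expected

    def test_too_few_shared_leaves_rejected(self):
        t1 = parse_newick("((a:1,b:1):1,c:1);")
        t2 = parse_newick("((a:1,b:1):1,d:1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestIdentityMatrix:
    def test_identical_pair_is_hundred(self):
        m = identity_matrix({"a": "ACGT", "b": "ACGT"})
        assert m.loc["a", "b"] == 100.0

    def test_direct_count(self):
        m = identity_matrix(Msa(taxa=["a", "b"], rows=["ACGT", "ACGA"]))
        assert m.loc["a", "b"] == 75.0

    @given(
        st.lists(
            st.text(alphabet="AVLW", min_size=4, max_size=8),
            min_size=2, max_size=4, unique=True,
        )
    )
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_symmetric_for_random_inputs(self, seqs):
        m = identity_matrix({f"s{i}": s for i, s in enumerate(seqs)})
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.all(np.diag(m.to_numpy()) == 100.0)


class TestPartitionTrees:
    def test_disjoint_partitions_build_one_tree_each(self):
        nwk = "((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2);"
        root = "".join(np.random.default_rng(4).choice(list(sim.AA20), 200))
        leaves = sim.evolve_on_tree(root, nwk, seed=9)
        msa = Msa(taxa=list(leaves), rows=list(leaves.values()))
        trees = partition_trees(msa, {"rt": (0, 100), "rle": (100, 200)})
        assert set(trees) == {"rt", "rle"}
        assert all(len(t.leaves()) == 4 for t in trees.values())

    def test_overlapping_partitions_rejected(self):
        msa = Msa(taxa=["a", "b", "c"], rows=["MKVLW", "MKVLW", "MKVLA"])
        with pytest.raises(ValueError, match="overlap"):
            partition_trees(msa, {"x": (0, 3), "y": (2, 5)})

    def test_out_of_bounds_partition_rejected(self):
        msa = Msa(taxa=["a", "b", "c"], rows=["MKVLW", "MKVLW", "MKVLA"])
        with pytest.raises(ValueError, match="bounds"):
            partition_trees(msa, {"x": (0, 9)})
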