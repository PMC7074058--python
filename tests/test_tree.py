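"""Neighbor-joining, bootstrap support, midpoint rooting, Newick round-trips."""

import numpy as np
import pytest

from _oracles import random_additive_tree
from taxodelim.matrix import DistanceMatrix
from taxodelim.mlsa import MarkerProfile
from taxodelim.tree import (
    NewickError,
    bootstrap_support,
    midpoint_root,
    neighbor_joining,
    parse_newick,
    patristic_distances,
    to_newick,
)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        # a = (dAB + dAC - dBC)/2 etc. -> 1, 1, 3
        dm = DistanceMatrix(
            ["A", "B", "C"], [[0, 2, 4], [2, 0, 4], [4, 4, 0]], "distance"
        )
        tree = neighbor_joining(dm)
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_matrices_recovered_exactly(self, rng):
        """NJ is consistent: generating topology and branch lengths come back."""
        for n in (5, 6, 7, 8):
            for _ in range(4):
                labels = [f"T{i}" for i in range(n)]
                nwk, D = random_additive_tree(labels, rng)
                truth = parse_newick(nwk)
                tree = neighbor_joining(DistanceMatrix(labels, D, "distance"))
                assert set(tree.bipartitions().values()) == set(
                    truth.bipartitions().values()
                )
                pat = patristic_distances(tree)
                truth_dm = DistanceMatrix(pat.labels, D, "distance")
                idx = [labels.index(l) for l in pat.labels]
                reordered = D[np.ix_(idx, idx)]
                assert np.allclose(pat.values, reordered, atol=1e-9)

    def test_agrees_with_independent_nj_on_additive_input(self, rng):
        import skbio

        labels = [f"T{i}" for i in range(6)]
        nwk, D = random_additive_tree(labels, rng)
        mine = neighbor_joining(DistanceMatrix(labels, D, "distance"))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        ref_splits = set()
        all_leaves = frozenset(labels)
        refleaf = min(labels)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if refleaf in side:
                side = all_leaves - side
            if 1 < len(side) < len(labels) - 1:
                ref_splits.add(side)
        assert set(mine.bipartitions().values()) == ref_splits

    def test_tie_break_is_deterministic(self):
        n = 5
        D = np.full((n, n), 3.0)
        np.fill_diagonal(D, 0.0)
        labels = [f"x{i}" for i in range(n)]
        t1 = to_newick(neighbor_joining(DistanceMatrix(labels, D, "distance")))
        t2 = to_newick(neighbor_joining(DistanceMatrix(labels, D, "distance")))
        assert t1 == t2

    def test_input_validation(self):
        dm = DistanceMatrix(["A", "B"], [[0, 1], [1, 0]], "distance")
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)
        pm = DistanceMatrix(
            ["A", "B", "C"],
            [[100, 99, 98], [99, 100, 97], [98, 97, 100]],
            "percent",
        )
        with pytest.raises(ValueError, match="distance-mode"):
            neighbor_joining(pm)


def _make_profiles(seqs_by_strain):
    return [
        MarkerProfile(s, {"16S": m16, "gyrB": g, "rpoB": r, "rpoD": d})
        for s, (m16, g, r, d) in seqs_by_strain.items()
    ]


class TestBootstrap:
    def _cluster_profiles(self, rng, between_div=0.1):
        base = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(4)]
        other = [
            "".join(
                c if rng.random() > between_div else {"A": "C", "C": "G", "G": "T", "T": "A"}[c]
                for c in m
            )
            for m in base
        ]
        return _make_profiles(
            {
                "a1": base, "a2": base, "a3": base,
                "b1": other, "b2": other, "b3": other,
            }
        )

    def test_no_variable_columns_gives_full_support(self, rng):
        base = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(4)]
        profiles = _make_profiles({f"s{i}": base for i in range(4)})
        tree = bootstrap_support(profiles, n_replicates=25, seed=0)
        for node, _ in tree.bipartitions().items():
            assert node.support == 100.0

    def test_seed_determinism_and_support_granularity(self, rng):
        profiles = self._cluster_profiles(rng)
        t1 = bootstrap_support(profiles, n_replicates=40, seed=5)
        t2 = bootstrap_support(profiles, n_replicates=40, seed=5)
        assert to_newick(t1) == to_newick(t2)
        for node in t1.bipartitions():
            assert 0.0 <= node.support <= 100.0
            assert (node.support * 40 / 100) == pytest.approx(
                round(node.support * 40 / 100)
            )

    def test_clear_separation_gets_full_support(self, rng):
        profiles = self._cluster_profiles(rng)
        tree = bootstrap_support(profiles, n_replicates=100, seed=1)
        split = frozenset(("b1", "b2", "b3"))
        supports = {
            bip: node.support for node, bip in tree.bipartitions().items()
        }
        assert supports[split] == 100.0

    def test_replicate_count_validation(self, rng):
        profiles = self._cluster_profiles(rng)
        with pytest.raises(ValueError):
            bootstrap_support(profiles, n_replicates=0)


class TestMidpointRoot:
    def test_two_leaf_midpoint(self):
        tree = midpoint_root(parse_newick("(A:1,B:3);"))
        assert tree.rooted
        lengths = sorted(c.length for c in tree.root.children)
        assert lengths == [2.0, 2.0]

    def test_symmetric_quartet_roots_on_central_edge(self):
        tree = midpoint_root(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        sides = [frozenset(l.name for l in c.leaves()) for c in tree.root.children]
        assert frozenset(("A", "B")) in sides
        assert frozenset(("C", "D")) in sides

    def test_root_balances_deepest_leaves(self, rng):
        for _ in range(10):
            labels = [f"L{i}" for i in range(10)]
            nwk, _ = random_additive_tree(labels, rng)
            rooted = midpoint_root(parse_newick(nwk))

            def depth(node, acc=0.0):
                if node.is_leaf:
                    return acc
                return max(depth(c, acc + c.length) for c in node.children)

            d = [
                (c.length or 0.0) + (depth(c) if not c.is_leaf else 0.0)
                for c in rooted.root.children
            ]
            assert abs(d[0] - d[1]) < 1e-9

    def test_all_zero_lengths_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            midpoint_root(parse_newick("(A:0,B:0,C:0);"))


class TestNewick:
    def test_parse_simple(self):
        tree = parse_newick("(A:1,B:3);")
        assert sorted(tree.leaf_names()) == ["A", "B"]
        assert {l.name: l.length for l in tree.leaves()} == {"A": 1.0, "B": 3.0}

    def test_support_preserved(self):
        text = "((A:1,B:1)90:2,C:3);"
        tree = parse_newick(text)
        internal = [n for n in tree.root.walk() if not n.is_leaf and n is not tree.root]
        assert internal[0].support == 90.0
        assert to_newick(tree) == text

    def test_emit_parse_emit_is_byte_stable(self):
        text = "((A:0.5,B:0.25)88:1.5,(C:2,D:0.1)95:0.75,E:3);"
        once = to_newick(parse_newick(text))
        twice = to_newick(parse_newick(once))
        assert once == twice == text

    @pytest.mark.parametrize("bad", ["(A:1,B:2)", "((A:1,B:2);", "(A:1,B:x);"])
    def test_malformed_input_reports_position(self, bad):
        with pytest.raises(NewickError) as exc:
            parse_newick(bad)
        assert exc.value.pos >= 0
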