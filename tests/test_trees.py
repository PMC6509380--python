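"""Tree structure, Newick I/O, distances, selection and clade support."""

import numpy as np
import pytest

import _oracles as oracles
from phylodiv.conditions import Condition
from phylodiv.trees import (
    NewickError, PhyloTree, TopologySet, bipartitions, clade_support,
    parse_newick, patristic_distances, rank_and_select, random_select,
    rf_distance, rf_to_backbone, write_newick,
)


class TestNewickIO:
    def test_two_tip_parse(self):
        (t,) = parse_newick("(A:1,B:1);")
        assert t.n_tips == 2
        assert set(t.tip_labels) == {"A", "B"}

    def test_roundtrip_identity(self, rng):
        t = oracles.random_binary_tree(rng, 9)
        t2 = PhyloTree.from_newick(t.to_newick())
        assert rf_distance(t, t2) == 0
        d1 = patristic_distances(t)
        d2 = patristic_distances(t2)
        assert np.allclose(d1.sort_index(axis=0).sort_index(axis=1),
                           d2.sort_index(axis=0).sort_index(axis=1))

    def test_total_branch_length(self, toy_tree):
        assert toy_tree.total_length == pytest.approx(5.0)

    def test_multi_tree_file(self, tmp_path, rng):
        trees = [oracles.random_binary_tree(rng, 6) for _ in range(4)]
        path = tmp_path / "set.nwk"
        write_newick(trees, path)
        back = parse_newick(path)
        assert len(back) == 4
        for a, b in zip(trees, back):
            assert rf_distance(a, b) == 0

    def test_malformed_raises(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,B:1;")

    def test_duplicate_tips_raise(self):
        with pytest.raises(NewickError, match="duplicate|[Mm]ultiple"):
            parse_newick("((A:1,A:1):1,C:1);")

    def test_missing_lengths_warn_default_zero(self):
        with pytest.warns(UserWarning, match="missing"):
            (t,) = parse_newick("((A,B):1,C:2);")
        assert t.total_length == pytest.approx(3.0)


class TestPatristic:
    def test_toy_values(self, toy_tree):
        d = patristic_distances(toy_tree)
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["B", "C"] == pytest.approx(4.0)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_matches_dendropy_on_random_trees(self, rng):
        for _ in range(10):
            t = oracles.random_binary_tree(rng, int(rng.integers(4, 10)))
            mine = patristic_distances(t)
            ref = oracles.dendropy_patristic(t)
            for (a, b), v in ref.items():
                assert mine.loc[a, b] == pytest.approx(v, abs=1e-10)


class TestRF:
    def test_self_distance_zero(self, rng):
        t = oracles.random_binary_tree(rng, 7)
        assert rf_distance(t, t.copy()) == 0

    def test_four_taxon_swap(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_resolved_vs_star(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        assert rf_distance(t1, star) == 1
        assert len(bipartitions(star)) == 0

    def test_tipset_mismatch_lists_difference(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        t2 = PhyloTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="C") as exc:
            rf_distance(t1, t2)
        assert "D" in str(exc.value)

    def test_matches_dendropy(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            t1 = oracles.random_binary_tree(rng, n, labels)
            t2 = oracles.random_binary_tree(rng, n, labels)
            assert rf_distance(t1, t2) == oracles.dendropy_rf(t1, t2)


class TestFamilyCondensation:
    def test_singleton_families_reduce_to_plain_rf(self, rng):
        n = 7
        labels = [f"t{i}" for i in range(n)]
        fam = {lab: f"F{lab}" for lab in labels}
        t = oracles.random_binary_tree(rng, n, labels)
        bb = oracles.random_binary_tree(rng, n, labels)
        # backbone with tips relabeled to the (singleton) family names
        relabeled = list(bb.labels)
        for i in bb.tip_indices:
            relabeled[i] = fam[bb.labels[i]]
        bb_fam = PhyloTree(bb.parent, bb.children, bb.lengths, relabeled)
        assert rf_to_backbone(t, bb_fam, fam) == rf_distance(t, bb)

    def test_perfect_match_gives_zero(self):
        sp = PhyloTree.from_newick(
            "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(c1:2,c2:2):1);"
        )
        fam = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
               "c1": "C", "c2": "C"}
        backbone = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        assert rf_to_backbone(sp, backbone, fam) == 0

    def test_broken_family_increases_distance(self):
        # family A straddles the deep split, so the species tree supports
        # {A,C}|{B,D} instead of the backbone's {A,B}|{C,D}
        sp = PhyloTree.from_newick(
            "(((a1:1,c1:1):1,(a2:1,c2:1):1):1,"
            "((b1:1,b2:1):1,(d1:1,d2:1):1):1);"
        )
        fam = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
               "c1": "C", "c2": "C", "d1": "D", "d2": "D"}
        backbone = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_to_backbone(sp, backbone, fam) == 2


class TestSelection:
    def _pool(self, rng, n_trees=12, n=6):
        labels = [f"t{i}" for i in range(n)]
        return [oracles.random_binary_tree(rng, n, labels)
                for _ in range(n_trees)]

    def test_identical_tree_ranks_first(self, rng):
        pool = self._pool(rng)
        backbone = pool[5].copy()
        sel = rank_and_select(pool, backbone, k=1)
        assert sel.rf_backbone[0] == 0
        assert rf_distance(sel.trees[0], backbone) == 0

    def test_distances_nondecreasing_and_stable(self, rng):
        pool = self._pool(rng, n_trees=20)
        backbone = oracles.random_binary_tree(
            rng, 6, [f"t{i}" for i in range(6)]
        )
        sel = rank_and_select(pool, backbone, k=10)
        assert sel.rf_backbone == sorted(sel.rf_backbone)
        # stability: equal-distance trees keep input order
        all_d = [rf_distance(t, backbone) for t in pool]
        expect = sorted(range(len(pool)), key=lambda i: all_d[i])[:10]
        got = [pool.index(t) for t in sel.trees]
        assert got == expect

    def test_k_too_large_errors(self, rng):
        pool = self._pool(rng, n_trees=3)
        with pytest.raises(ValueError):
            rank_and_select(pool, pool[0], k=4)
        with pytest.raises(ValueError):
            random_select(pool, k=4, seed=0)

    def test_random_select_deterministic(self, rng):
        pool = self._pool(rng, n_trees=10)
        a = random_select(pool, 4, seed=77)
        b = random_select(pool, 4, seed=77)
        assert [id(x) for x in a.trees] == [id(x) for x in b.trees]

    def test_random_select_uniform_frequency(self, rng):
        pool = self._pool(rng, n_trees=8)
        counts = np.zeros(8)
        reps = 400
        for s in range(reps):
            sel = random_select(pool, 2, seed=s)
            for t in sel.trees:
                counts[pool.index(t)] += 1
        freq = counts / reps
        # binomial 99.9% band around k/n = 0.25
        se = np.sqrt(0.25 * 0.75 / reps)
        assert np.all(np.abs(freq - 0.25) < 4 * se)


class TestCladeSupport:
    def test_identical_trees_full_support(self, rng):
        t = oracles.random_binary_tree(rng, 7)
        sup = clade_support(TopologySet([t.copy() for _ in range(5)]))
        assert sup and all(v == 1.0 for v in sup.values())

    def test_frequency_counts(self, rng):
        labels = [f"t{i}" for i in range(6)]
        t1 = oracles.random_binary_tree(rng, 6, labels)
        t2 = oracles.random_binary_tree(rng, 6, labels)
        trees = [t1] * 3 + [t2] * 1
        sup = clade_support(TopologySet(trees))
        s1, s2 = bipartitions(t1), bipartitions(t2)
        for split in s1 - s2:
            assert sup[split] == pytest.approx(0.75)
        for split in s2 - s1:
            assert sup[split] == pytest.approx(0.25)
        for split in s1 & s2:
            assert sup[split] == pytest.approx(1.0)
        assert not (set(sup) - (s1 | s2))


class TestTopologySet:
    def test_mismatched_tips_rejected(self, rng):
        t1 = oracles.random_binary_tree(rng, 5, list("abcde"))
        t2 = oracles.random_binary_tree(rng, 5, list("abcdf"))
        with pytest.raises(ValueError):
            TopologySet([t1, t2])

    def test_condition_attached(self, rng):
        cond = Condition.from_label("R+M+I+B")
        ts = TopologySet([oracles.random_binary_tree(rng, 4)], condition=cond)
        assert ts.condition.has_backbone and ts.condition.has_ITS
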