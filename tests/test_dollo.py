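"""Dollo parsimony: reconstruction, constraints, bookkeeping, group sets."""

import numpy as np
import pytest

from ncranno.dollo import (PresenceMatrix, dollo_reconstruct,
                           edge_and_node_summary, family_sets, load_tree,
                           read_presence_matrix, species_tree,
                           write_presence_matrix)
from oracles import dollo_min_losses


@pytest.fixture(scope="module")
def tree():
    return load_tree("((a,b)ab,((c,d)cd,e)cde)root;")


def one_family(tree, presence, name="f"):
    cells = np.array([[1 if t in presence else 0 for t in tree.leaves]])
    return PresenceMatrix([name], list(tree.leaves), cells)


class TestReconstruction:
    def test_ubiquitous_family_gains_at_root_no_losses(self, tree):
        rec = dollo_reconstruct(tree, one_family(tree, set(tree.leaves)))
        assert rec.gain_node["f"] == "root"
        assert rec.loss_edges["f"] == set()
        assert all(v == 1 for v in rec.states["f"].values())

    def test_singleton_family_gains_on_pendant_edge(self, tree):
        rec = dollo_reconstruct(tree, one_family(tree, {"c"}))
        assert rec.gain_node["f"] == "c"
        assert rec.loss_edges["f"] == set()
        assert sum(rec.states["f"].values()) == 1

    def test_loss_counts_match_exhaustive_minimum(self):
        """Random trees x random columns: the reconstruction's loss count
        equals the brute-force single-gain minimum."""
        rng = np.random.default_rng(13)
        newicks = [
            "((a,b)ab,((c,d)cd,(e,(f,g)fg)efg)x)root;",
            "(((a,b)ab,(c,d)cd)abcd,((e,f)ef,(g,h)gh)efgh)root;",
            "((a,(b,(c,d)cd)bcd)abcd,(e,f)ef)root;",
        ]
        for nwk in newicks:
            t = load_tree(nwk)
            for _ in range(70):
                col = {l: int(rng.integers(2)) for l in t.leaves}
                m = one_family(t, {l for l, v in col.items() if v})
                rec = dollo_reconstruct(t, m)
                mine = (len(rec.loss_edges["f"])
                        if rec.gain_node["f"] is not None else None)
                assert mine == dollo_min_losses(t, col)

    def test_single_gain_invariants(self, tree):
        rng = np.random.default_rng(29)
        for _ in range(40):
            pres = {l for l in tree.leaves if rng.random() < 0.5}
            rec = dollo_reconstruct(tree, one_family(tree, pres))
            if not pres:
                assert rec.gain_node["f"] is None
                continue
            st = rec.states["f"]
            # leaves match, no loss edge is also the gain edge
            for l in tree.leaves:
                assert st[l] == (l in pres)
            assert rec.gain_node["f"] not in rec.loss_edges["f"]

    def test_determinism(self, tree):
        m = one_family(tree, {"a", "c", "e"})
        r1 = dollo_reconstruct(tree, m)
        r2 = dollo_reconstruct(tree, m)
        assert r1.states == r2.states and r1.loss_edges == r2.loss_edges


class TestConstraints:
    def test_forced_presence_relocates_gain(self, tree):
        m = one_family(tree, {"c"})
        rec = dollo_reconstruct(tree, m, constraints={("root", "f"): 1})
        assert rec.gain_node["f"] == "root"
        # losses now separate the absent subtrees from the forced root
        assert "ab" in rec.loss_edges["f"]

    def test_leaf_contradiction_is_an_error(self, tree):
        m = one_family(tree, {"c"})
        with pytest.raises(ValueError, match="contradicts"):
            dollo_reconstruct(tree, m, constraints={("c", "f"): 0})

    def test_forced_absence_above_presence_is_an_error(self, tree):
        m = one_family(tree, {"c", "d"})
        with pytest.raises(ValueError, match="contradicts"):
            dollo_reconstruct(tree, m, constraints={("cd", "f"): 0})

    def test_taxa_mismatch_rejected(self, tree):
        m = PresenceMatrix(["f"], ["a", "b", "zzz", "d", "e"],
                           np.ones((1, 5), dtype=int))
        with pytest.raises(ValueError, match="do not match"):
            dollo_reconstruct(tree, m)


class TestSummary:
    def test_path_identity_on_every_edge(self, tree):
        rng = np.random.default_rng(41)
        fams = [f"f{i}" for i in range(30)]
        cells = rng.integers(0, 2, size=(30, len(tree.leaves)))
        m = PresenceMatrix(fams, list(tree.leaves), cells)
        rec = dollo_reconstruct(tree, m)
        nodes, edges = edge_and_node_summary(rec)
        for row in edges.itertuples():
            assert nodes.loc[row.child, "families"] == \
                nodes.loc[row.parent, "families"] + row.gains - row.losses

    def test_all_zero_matrix(self, tree):
        m = PresenceMatrix(["f1", "f2"], list(tree.leaves),
                           np.zeros((2, 5), dtype=int))
        nodes, edges = edge_and_node_summary(dollo_reconstruct(tree, m))
        assert (nodes["families"] == 0).all()
        assert (edges[["gains", "losses"]] == 0).all().all()


class TestFamilySets:
    def test_partition_identity(self, tree):
        rng = np.random.default_rng(47)
        fams = [f"f{i}" for i in range(40)]
        cells = rng.integers(0, 2, size=(40, len(tree.leaves)))
        m = PresenceMatrix(fams, list(tree.leaves), cells)
        a, b = {"a", "b"}, {"c", "e"}
        shared, a_spec, b_spec = family_sets(m, a, b)
        present_union = {
            f for i, f in enumerate(fams)
            if any(cells[i, m.taxa.index(t)] for t in a | b)
        }
        assert shared | a_spec | b_spec == present_union
        assert not (shared & a_spec or shared & b_spec or a_spec & b_spec)

    def test_exclusive_membership(self, tree):
        m = one_family(tree, {"a"})
        shared, a_spec, b_spec = family_sets(m, {"a"}, {"c"})
        assert (shared, a_spec, b_spec) == (set(), {"f"}, set())

    def test_absent_family_in_no_set(self, tree):
        m = one_family(tree, set())
        assert family_sets(m, {"a"}, {"c"}) == (set(), set(), set())

    def test_overlapping_groups_rejected(self, tree):
        with pytest.raises(ValueError, match="overlap"):
            family_sets(one_family(tree, {"a"}), {"a", "b"}, {"b", "c"})


class TestFixtureTreeAndIo:
    def test_bundled_topology(self):
        t = species_tree()
        assert set(t.leaves) == {"Cel", "Bfl", "Odi", "Bsc", "Dvex", "Cin",
                                 "Csa", "Pma", "Dre", "Lch", "Xtr", "Aca"}
        for name in ("Bilateria", "Chordata", "Olfactores", "Tunicata",
                     "Craniata"):
            assert name in t.preorder
        assert t.subtree_leaves("Tunicata") == {"Odi", "Bsc", "Dvex", "Cin",
                                                "Csa"}

    def test_matrix_round_trip(self, tree, tmp_path):
        rng = np.random.default_rng(3)
        m = PresenceMatrix(["fam1", "fam2"], list(tree.leaves),
                           rng.integers(0, 2, size=(2, 5)),
                           {"fam1": "miRNA", "fam2": "snoRNA"})
        p = tmp_path / "m.tsv"
        write_presence_matrix(m, p)
        back = read_presence_matrix(p)
        assert back.families == m.families and back.taxa == m.taxa
        assert (back.cells == m.cells).all()
        assert back.class_of == m.class_of
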