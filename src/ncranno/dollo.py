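"""Dollo-parsimony reconstruction of gene-family histories on a rooted
species tree: each family is gained exactly once (at the most recent common
ancestor of the taxa carrying it, or higher when prior knowledge constrains
an ancestral node) and may be lost independently on any number of edges.

Hard constraints override parsimony placement: ancestral states asserted
from published phylogenetic distributions are taken as given, not inferred.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "PresenceMatrix",
    "DolloReconstruction",
    "load_tree",
    "species_tree",
    "dollo_reconstruct",
    "edge_and_node_summary",
    "family_sets",
    "read_presence_matrix",
    "write_presence_matrix",
]


class Tree:
    """A rooted tree with uniquely named nodes (thin wrapper over dendropy).

    Unnamed internal nodes are auto-labelled ``nodeN`` in preorder.
    """

    def __init__(self, dtree: dendropy.Tree):
        self.parent: dict[str, str | None] = {}
        self.children: dict[str, list[str]] = {}
        self.leaves: list[str] = []
        self.preorder: list[str] = []
        counter = 0
        names: dict[int, str] = {}
        for node in dtree.preorder_node_iter():
            if node.taxon is not None and node.taxon.label:
                label = node.taxon.label.replace(" ", "_")
            elif node.label:
                label = node.label.replace(" ", "_")
            else:
                label = f"node{counter}"
            counter += 1
            if label in self.parent:
                raise ValueError(f"duplicate node label {label!r}")
            names[id(node)] = label
            parent = (names[id(node.parent_node)]
                      if node.parent_node is not None else None)
            self.parent[label] = parent
            self.children[label] = []
            if parent is not None:
                self.children[parent].append(label)
            self.preorder.append(label)
            if node.is_leaf():
                self.leaves.append(label)
        self.root = self.preorder[0]

    def path_to_root(self, label: str) -> list[str]:
        out = [label]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])
        return out

    def mrca(self, labels) -> str:
        labels = list(labels)
        common = set(self.path_to_root(labels[0]))
        for l in labels[1:]:
            common &= set(self.path_to_root(l))
        # first common node on the upward path is the MRCA
        for node in self.path_to_root(labels[0]):
            if node in common:
                return node
        return self.root

    def subtree_leaves(self, label: str) -> set[str]:
        out = set()
        stack = [label]
        while stack:
            v = stack.pop()
            kids = self.children[v]
            if not kids:
                out.add(v)
            stack.extend(kids)
        return out


def load_tree(source: str) -> Tree:
    """Parse a rooted Newick tree (path or literal string)."""
    data = source
    if "\n" not in source and not source.strip().startswith("("):
        with open(source) as fh:
            data = fh.read()
    dtree = dendropy.Tree.get(data=data, schema="newick",
                              suppress_internal_node_taxa=True)
    return Tree(dtree)


def species_tree() -> Tree:
    """The bilaterian species topology used for the comparative analysis,
    shipped as an editable Newick fixture."""
    ref = importlib.resources.files("ncranno").joinpath("data/species_tree.nwk")
    return load_tree(ref.read_text())


@dataclass
class PresenceMatrix:
    families: list[str]
    taxa: list[str]
    cells: np.ndarray                      # (families, taxa) in {0, 1}
    class_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int)
        if self.cells.shape != (len(self.families), len(self.taxa)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("presence values must be 0 or 1")

    def presence(self, family: str) -> set[str]:
        row = self.cells[self.families.index(family)]
        return {t for t, v in zip(self.taxa, row) if v}


def read_presence_matrix(path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    class_of = {}
    if "rna_class" in df.columns:
        class_of = df["rna_class"].to_dict()
        df = df.drop(columns=["rna_class"])
    return PresenceMatrix(list(df.index), list(df.columns),
                          df.to_numpy(), class_of)


def write_presence_matrix(matrix: PresenceMatrix, path) -> None:
    df = pd.DataFrame(matrix.cells, index=matrix.families,
                      columns=matrix.taxa)
    if matrix.class_of:
        df.insert(0, "rna_class",
                  [matrix.class_of.get(f, "") for f in matrix.families])
    df.to_csv(path, sep="\t")


@dataclass
class DolloReconstruction:
    tree: Tree
    families: list[str]
    states: dict[str, dict[str, int]]       # family -> node -> {0,1}
    gain_node: dict[str, str | None]        # family -> node where it arises
    loss_edges: dict[str, set[str]]         # family -> child labels of loss edges


def dollo_reconstruct(tree: Tree, matrix: PresenceMatrix,
                      constraints: dict | None = None) -> DolloReconstruction:
    """Single-gain/multiple-loss reconstruction for every family.

    ``constraints`` maps ``(node_label, family_id)`` to a forced state.  A
    forced presence above the parsimony gain node relocates the gain to the
    most recent common ancestor of all forced and observed presences; a
    forced state contradicting a leaf observation (or an observed presence
    below a forced absence) is an error.  A node is present iff it lies on a
    path from the gain node to a presence leaf or forced-present node.
    Losses are the edges from a present parent into an absent subtree; this
    minimizes losses subject to the single-gain rule.
    """
    if set(matrix.taxa) != set(tree.leaves):
        raise ValueError(
            "matrix taxa do not match tree leaves: "
            f"{sorted(set(matrix.taxa) ^ set(tree.leaves))}"
        )
    constraints = constraints or {}
    states: dict[str, dict[str, int]] = {}
    gain_node: dict[str, str | None] = {}
    loss_edges: dict[str, set[str]] = {}
    for fi, fam in enumerate(matrix.families):
        leaf_state = {t: int(matrix.cells[fi, ti])
                      for ti, t in enumerate(matrix.taxa)}
        forced = {node: val for (node, f), val in constraints.items()
                  if f == fam}
        for node, val in forced.items():
            if node not in tree.parent:
                raise ValueError(f"constraint on unknown node {node!r}")
            if node in leaf_state and leaf_state[node] != val:
                raise ValueError(
                    f"constraint on leaf {node} contradicts the observed "
                    f"state for family {fam}"
                )
        targets = {t for t, v in leaf_state.items() if v}
        targets |= {n for n, v in forced.items() if v == 1}
        if not targets:
            states[fam] = {n: 0 for n in tree.preorder}
            gain_node[fam] = None
            loss_edges[fam] = set()
            continue
        gain = tree.mrca(targets)
        present: set[str] = set()
        for t in targets:
            path = tree.path_to_root(t)
            present.update(path[: path.index(gain) + 1])
        for node, val in forced.items():
            if val == 0:
                below = tree.subtree_leaves(node)
                if below & targets or node in present:
                    raise ValueError(
                        f"forced absence at {node} contradicts presence "
                        f"below it for family {fam}"
                    )
        states[fam] = {n: int(n in present) for n in tree.preorder}
        gain_node[fam] = gain
        loss_edges[fam] = {
            n for n in tree.preorder
            if n not in present and tree.parent[n] is not None
            and tree.parent[n] in present
        }
    return DolloReconstruction(tree, list(matrix.families), states,
                               gain_node, loss_edges)


def edge_and_node_summary(recon: DolloReconstruction):
    """Aggregate counts: per-node family totals, per-edge gains and losses.

    Returns ``(node_counts, edge_events)`` DataFrames.  On every edge the
    bookkeeping identity holds:
    ``count(child) = count(parent) + gains(edge) - losses(edge)``.
    """
    tree = recon.tree
    counts = {n: 0 for n in tree.preorder}
    gains = {n: 0 for n in tree.preorder}
    losses = {n: 0 for n in tree.preorder}
    for fam in recon.families:
        st = recon.states[fam]
        for n in tree.preorder:
            counts[n] += st[n]
        g = recon.gain_node[fam]
        if g is not None:
            gains[g] += 1
        for e in recon.loss_edges[fam]:
            losses[e] += 1
    node_counts = pd.DataFrame(
        {"node": list(tree.preorder),
         "families": [counts[n] for n in tree.preorder]}
    ).set_index("node")
    rows = []
    for n in tree.preorder:
        if tree.parent[n] is None:
            continue
        rows.append({"parent": tree.parent[n], "child": n,
                     "gains": gains[n], "losses": losses[n]})
    edge_events = pd.DataFrame(rows)
    return node_counts, edge_events


def family_sets(matrix: PresenceMatrix, group_a: set, group_b: set):
    """Families shared between and specific to two disjoint taxon groups.

    ``a_specific``: present in at least one member of A and in no member of
    B (and symmetrically); ``shared``: present in at least one member of
    each.  Families absent from both groups appear in none of the sets.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    unknown = (group_a | group_b) - set(matrix.taxa)
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    ai = [matrix.taxa.index(t) for t in sorted(group_a)]
    bi = [matrix.taxa.index(t) for t in sorted(group_b)]
    shared, a_spec, b_spec = set(), set(), set()
    for fi, fam in enumerate(matrix.families):
        in_a = bool(matrix.cells[fi, ai].any())
        in_b = bool(matrix.cells[fi, bi].any())
        if in_a and in_b:
            shared.add(fam)
        elif in_a:
            a_spec.add(fam)
        elif in_b:
            b_spec.add(fam)
    return shared, a_spec, b_spec
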