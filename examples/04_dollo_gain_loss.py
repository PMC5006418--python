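"""Dollo-parsimony family history on the bundled bilaterian topology.

Builds a tiny presence/absence matrix for four hypothetical families over
the 12 species in the fixture tree, reconstructs each family's single gain
and its losses, and prints per-node family counts and per-edge events.
On every edge, count(child) = count(parent) + gains - losses.
"""

import numpy as np

from ncranno.dollo import (PresenceMatrix, dollo_reconstruct,
                           edge_and_node_summary, family_sets, species_tree)

tree = species_tree()
taxa = list(tree.leaves)
rows = {
    "let7-like":  set(taxa),                          # ubiquitous
    "mir-col":    {"Dvex", "Bsc"},                    # colonial tunicates
    "mir-sol":    {"Cin", "Csa", "Odi"},              # solitary tunicates
    "snoZ-like":  {"Dre", "Lch", "Xtr", "Aca", "Pma"},  # craniate-only
}
matrix = PresenceMatrix(
    list(rows), taxa,
    np.array([[1 if t in rows[f] else 0 for t in taxa] for f in rows]))

recon = dollo_reconstruct(tree, matrix)
for fam in rows:
    print(f"{fam}: gained at {recon.gain_node[fam]}, "
          f"lost on {sorted(recon.loss_edges[fam]) or 'no'} edges")
nodes, edges = edge_and_node_summary(recon)
print("\nfamilies present per ancestral node:")
print(nodes[nodes["families"] > 0].to_string())
print("\nedges with events (gains/losses):")
print(edges[(edges.gains > 0) | (edges.losses > 0)].to_string(index=False))

shared, colonial, solitary = family_sets(matrix, {"Dvex", "Bsc"},
                                         {"Cin", "Csa", "Odi"})
print(f"\ncolonial-specific: {sorted(colonial)}; "
      f"solitary-specific: {sorted(solitary)}; shared: {sorted(shared)}")
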