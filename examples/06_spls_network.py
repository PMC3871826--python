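"""sPLS network linking the protein-spot block to the rest of the panel.

Protein-spot volumes (X) predict metabolites, enzyme activities and
phenotypes (Y) through sparse latent components; the similarity matrix
reconstructed from the latent variates is thresholded at 0.7 into a signed
bipartite network.  A lagged variant connects early-stage proteins to
late-stage composition.
"""

import warnings

import panelomics as po

warnings.filterwarnings("ignore")

table, _, truth = po.generate_panel(po.PanelConfig(seed=1))

model, M, net = po.spls_network(table, "OR", n_components=3, threshold=0.7)
print(f"within-OR network: {net.n_nodes} nodes, {net.n_edges} edges")
print(f"retained per component: keep_x={model.keep_x}, keep_y={model.keep_y}")
top = sorted(net.edges, key=lambda e: -abs(e.weight))[:5]
for e in top:
    print(f"  {e.node_a:10s} -- {e.node_b:10s}  similarity {e.weight:+.2f}")

_, _, lag = po.lagged_network(table, "CE", "OR", n_components=3, threshold=0.7)
print(f"\nlagged CE-proteins -> OR-composition network: {lag.n_edges} edges")
# Edges with |similarity| >= 0.7 mirror strong trait-spot correlations; the
# sparsity keeps noise spots out of the loading vectors.
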