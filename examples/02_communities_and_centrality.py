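"""Community structure, centrality and the MST backbone of a network.

Detects walktrap communities of the estimated network, summarises
within/between-community connectivity (RMSEW), ranks nodes by strength,
eigencentrality and bridge strength, and extracts the minimum-spanning-tree
backbone from Gower distances on the partial correlations.
"""

import ordnet

model = ordnet.generate_true_ggm(seed=1)
data = ordnet.sample_ordinal(model, n=1000, seed=2)
net = ordnet.select_network(ordnet.correlation_matrix(data))

comm = ordnet.walktrap(net)
print(f"walktrap found {comm.n_communities} communities "
      f"(modularity {comm.modularity:.2f})")
print("community sizes:", dict(zip(*__import__('numpy').unique(comm.labels,
                                                              return_counts=True))))

print("\nblock connectivity (root mean squared edge weight):")
print(ordnet.rmsew(net, comm).round(3).to_string(index=False))
# Within-community RMSEW should clearly exceed between-community RMSEW.

tbl = ordnet.centrality_table(net, comm.labels)
print("\ntop nodes by strength z-score:")
print(tbl.nlargest(3, "strength_z")[
    ["variable", "strength_z", "eigencentrality_z", "bridge_strength_z"]
].round(2).to_string(index=False))

tree = ordnet.mst_backbone(net)
cross = sum(1 for i, j, *_ in tree.edges if comm.labels[i] != comm.labels[j])
print(f"\nMST backbone: {len(tree.edges)} edges, {cross} of them crossing "
      "community boundaries")
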