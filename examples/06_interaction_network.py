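"""Build and summarize the bipartite DBS / Ligand-Cluster network.

Nodes are binding sites (with promiscuity and protein class) and ligand
clusters; an edge means one ligand of the cluster contacts one pocket of
the site.  Ligand clusters of degree 1 are selective, others promiscuous.
"""

from promisite import build_network, subnetwork, tabulate

dbs = {
    "L1_1": {"promiscuity": "S", "n_pockets": 4, "protein_class": "lyase"},
    "L1_2": {"promiscuity": "HP", "n_pockets": 9, "protein_class": "lyase"},
    "H1_1": {"promiscuity": "MP", "n_pockets": 5, "protein_class": "hydrolase"},
    "T1_1": {"promiscuity": "HP", "n_pockets": 7, "protein_class": "transferase"},
}
edges = [("L1_1", "LC1"), ("L1_2", "LC2"), ("L1_2", "LC3"), ("L1_2", "LC4"),
         ("L1_2", "LC5"), ("H1_1", "LC5"), ("H1_1", "LC6"), ("T1_1", "LC2"),
         ("T1_1", "LC6"), ("T1_1", "LC7"), ("T1_1", "LC8"), ("T1_1", "LC9")]
g = build_network(dbs, edges)
tables = tabulate(g)
print(tables["dbs_promiscuity"].to_string(index=False))
print(tables["ligand_cluster_promiscuity"].to_string(index=False))

sub = subnetwork(g, protein_class="lyase")
print("lyase two-step subnetwork nodes:", sorted(sub.nodes))
# LC5 bridges a lyase site to a hydrolase site and LC2 to a transferase
# site, so the lyase expansion pulls in H1_1 and T1_1: shared ligand
# types interconnect protein classes.
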