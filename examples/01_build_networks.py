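"""Build the four co-occurrence networks on one synthetic community.

Generates a 30-taxon community (10 planted direct dependencies, 5 chains,
5% detection dropout, 500 samples) and compares what each construction
strategy recovers.
"""

from metanet import (
    build_fsweight_network,
    build_loose_network,
    build_strict_network,
    generate_community,
    ground_truth_metrics,
    pca_pmi_network,
    random_spec,
)

spec = random_spec(30, 500, n_direct=10, n_chains=5, dropout=0.05, seed=42)
abundance, truth = generate_community(spec)
print(f"community: {abundance.shape[0]} taxa x {abundance.shape[1]} samples, "
      f"{truth.number_of_edges()} planted dependencies\n")

networks = {
    "pearson (strict)": build_strict_network(abundance),
    "loose": build_loose_network(abundance),
    "pcapmi": pca_pmi_network(abundance),
}
networks["fsweight"] = build_fsweight_network(networks["loose"])

for name, net in networks.items():
    precision, recall, f1 = ground_truth_metrics(net, truth)
    print(f"{name:18s} {net.number_of_nodes():3d} nodes {net.number_of_edges():3d} edges"
          f"   precision {precision:.2f}  recall {recall:.2f}")

print("\nThe strict network demands joint presence in every sample, so a few")
print("detection zeros per taxon empty it entirely (recall 0; its vacuous")
print("precision of 1 just means it made no claims). The loose gate")
print("(co-occurrence >= 0.8) recovers the planted structure, FS-Weight")
print("re-scores it by shared neighborhoods, and the PMI network tests every")
print("edge against conditioning sets to prune chain shortcuts.")
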