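"""Network propagation and disease-module detection on a planted network.

Builds a planted-partition interactome (3 communities), seeds the
propagation with genes from one community, and runs personalized PageRank
-> top-quartile threshold -> walktrap -> KS module significance.
"""

from lipscreen import synthetic
from lipscreen.enrichment import jaccard_index
from lipscreen.network import propagate_and_detect

net, seed_sets, truth = synthetic.generate_module_network(
    n_nodes=60, n_modules=3, p_in=0.6, p_out=0.02, n_seeds_per_module=5, seed=11
)
seeds = seed_sets[0]
print(f"network: {len(net.nodes)} nodes, {net.graph.number_of_edges()} edges; "
      f"seeds: {sorted(seeds)}")

modules, scores = propagate_and_detect(net, seeds)
print(f"PageRank mass: {sum(scores.values()):.12f}")

target = {n for n, m in truth.module_assignments.items() if m == 0}
for k, mod in enumerate(modules):
    print(f"module {k}: {len(mod.member_nodes):2d} nodes, "
          f"{len(mod.seed_hits)} seed hits, KS q = {mod.ks_q:.2e}, "
          f"selected={mod.selected}, "
          f"Jaccard vs planted community = "
          f"{jaccard_index(set(mod.member_nodes), target):.2f}")

print("\nA module is selected when it has >= 10 nodes, >= 1 seed gene and")
print("adjusted KS p < 0.05 for elevated propagation scores inside it.")
print("Note the strict top-quartile threshold keeps at most a quarter of the")
print("network, and the max-modularity cut often splits dense random")
print("communities, so single detected modules cover the planted community")
print("only partially (see docs/methods.md).")
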