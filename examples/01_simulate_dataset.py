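"""Simulate a single-cell dataset with a known regulatory ground truth.

Draws a sparse TF -> gene network with hub TFs, then generates
overdispersed counts with dropout whose latent structure follows the
network along pseudotime.
"""

import numpy as np

from grnimpact import SimulationConfig, sample_ground_truth, simulate_counts

cfg = SimulationConfig(n_tfs=10, n_genes=100, n_cells=300, edges_per_gene=2.0,
                       effect_size=2.0, seed=42)
net = sample_ground_truth(cfg)
data = simulate_counts(net, cfg)

out_degree = {}
for s, _ in net.edges:
    out_degree[s] = out_degree.get(s, 0) + 1

print(f"network: {len(net.tfs)} TFs, {len(net.genes)} genes, "
      f"{net.n_edges} true edges (density {net.density():.3f})")
print(f"hub TF out-degrees: {sorted(out_degree.values(), reverse=True)[:5]} "
      "(heavy-tailed: a few TFs regulate many targets)")
print(f"counts: {data.n_genes} x {data.n_cells}, "
      f"{(data.counts == 0).mean():.0%} zeros, "
      f"median library {int(np.median(data.counts.sum(axis=0)))}")
print("zeros combine sampling noise and mean-dependent technical dropout, "
      "the two nuisances imputation tries to undo")
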