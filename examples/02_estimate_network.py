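"""EBIC graphical-lasso network estimation and node centrality.

Samples skewed ordinal data from a known sparse partial-correlation
network, re-estimates the network, and prints the selected penalty, the
recovered edges, and the centrality table (strength, expected influence,
closeness, betweenness, predictability R^2).
"""

import numpy as np

import symptomnet as sn

truth = sn.make_true_network(
    sn.TrueNetworkSpec(p=9, density=0.3, weight_range=(0.2, 0.4), seed=11)
)
data = sn.sample_ordinal_dataset(truth, sn.default_emulation(p=9, n=2000), seed=5)

net = sn.estimate_network(data)  # gamma = 0.5, 100-step penalty path
print(f"selected lambda = {net.lam:.4f}, edges = {net.edge_count}, "
      f"EBIC = {net.ebic:.1f}")

iu = np.triu_indices(net.p, 1)
r = np.corrcoef(truth.weights[iu], net.weights[iu])[0, 1]
print(f"correlation with true edge weights: {r:.3f}")
# ~0.95+ at n = 2000: the penalized estimate tracks the generating network

print("\nstrongest recovered edges:")
for u, v, w in sorted(net.edge_list(), key=lambda e: -abs(e[2]))[:5]:
    print(f"  {u} -- {v}: {w:+.3f}")

print("\ncentrality table:")
print(sn.centrality_table(net, data).round(2).to_string())
# strength = expected influence here because every edge is positive
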