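"""Flow view of a network around a focal node.

Estimates an 11-node network (nine depression symptoms plus the two
intolerance-of-uncertainty dimensions, prospective anxiety AA and
inhibitory anxiety IA) and partitions the symptoms into those directly
connected to a focal node and those reachable only through
intermediaries.
"""

import json

import symptomnet as sn

truth = sn.make_true_network(sn.TrueNetworkSpec(p=11, density=0.3, seed=8))
data = sn.sample_ordinal_dataset(truth, sn.default_emulation(p=11, n=1500), seed=9)
net = sn.estimate_network(data)

for focal in ("IA", "PHQ9"):
    dec = sn.flow_decompose(net, focal)
    print(f"\nfocal node {focal}:")
    print(json.dumps(dec.to_dict(), indent=1))
    # 'direct' nodes share an edge with the focal node; each indirect layer
    # is one more step away; 'edges_to_focal' ranks the direct links by
    # |partial correlation|, the usual reading of a flow diagram
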