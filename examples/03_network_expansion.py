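"""Rank candidate genes by network diffusion from known effect genes.

Builds a 2000-node scale-free network with a 50-gene planted module, seeds
the diffusion with 40 module members, and shows (a) cross-validated
recovery of held-out seeds and (b) the top-ranked unlabelled genes —
which should be the 10 module members that were never labelled.
"""

import numpy as np

from oatargets import build_network, cross_validate, diffuse, rank_genes
from oatargets.synthdata import synth_network

edges, truth = synth_network(
    n_nodes=2000, module_size=50, intra_module_edge_prob=0.5, rng_seed=11
)
network = build_network(edges)
seeds = truth.planted_module[:40]
hidden = set(truth.planted_module[40:])

cv = cross_validate(network, seeds, k=5, repeats=5, rng_seed=11)
print(f"median held-out seed rank: {np.median(cv.heldout_ranks):.0f} "
      f"of {network.n_nodes} (unlabelled genes: "
      f"{np.median(cv.unlabelled_ranks):.0f})")
# a held-out seed ranking far above the ~n/2 random expectation means the
# module structure alone predicts membership

scores = diffuse(network, seeds, r=0.3)
ranks = rank_genes(scores, exclude=seeds)
top10 = sorted(ranks, key=ranks.get)[:10]
recovered = sum(g in hidden for g in top10)
print(f"top 10 ranked unlabelled genes: {top10}")
print(f"{recovered}/10 are hidden module members")
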