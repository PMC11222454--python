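"""Bipartite bi-clustering of an mRNA x time-point response matrix.

Plants a block of 8 genes responding at two time-points inside a noisy
background, builds the thresholded bipartite response graph, searches for
heavy modules, applies the 10% overlap filter and merges modules per
time-point.
"""

import numpy as np
import pandas as pd

from temponet.bicluster import (
    build_response_graph,
    filter_overlap,
    find_biclusters,
    merge_per_timepoint,
)

rng = np.random.default_rng(3)
genes = [f"Gene{i}" for i in range(40)]
conds = ["24h", "72h", "10d", "DOFS", "Chronic"]
responses = rng.normal(size=(40, 5, 3)).mean(axis=2)  # 3 replicates averaged
responses[:8, :2] += 3.0  # planted module: genes 0-7 at 24h & 72h

profile = pd.DataFrame(responses, index=genes, columns=conds)
edges = build_response_graph(profile, response_threshold=1.5)
modules = filter_overlap(find_biclusters(edges, seed=0), max_overlap=0.10)

print(f"response graph: {len(edges)} (gene, time-point) edges")
for i, mod in enumerate(modules[:3], 1):
    print(f"module {i}: weight {mod.weight:6.1f}  "
          f"conditions {sorted(mod.conditions)}  genes {sorted(mod.mrnas)}")
for tp in ("24h", "10d"):
    print(f"merged mRNA set at {tp}: {sorted(merge_per_timepoint(modules, tp))}")
print("The top module recovers the planted 8-gene block; merged per-time-point "
      "sets feed the Bayesian model at each time-point.")
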