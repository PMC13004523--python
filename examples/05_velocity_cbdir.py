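"""Cross-boundary direction correctness (CBDir) on a synthetic embedding.

CBDir scores whether velocity vectors of cells at the boundary between two
clusters point toward the known downstream cluster: the cosine between a
boundary cell's velocity and its displacement to each target-cluster
neighbor, averaged per cell and then over boundary cells. +1 means
velocities agree perfectly with the ground-truth transition, -1 means they
point backwards.
"""

import numpy as np

from priornmf import Embedding, cbdir, knn_graph

rng = np.random.default_rng(0)
# two adjacent clusters along the x axis: "progenitor" at x~0 flowing toward
# "mature" at x~2, close enough that their edges share nearest neighbors
coords = np.vstack([
    rng.normal([0, 0], 0.7, size=(30, 2)),
    rng.normal([2, 0], 0.7, size=(30, 2)),
])
labels = ["progenitor"] * 30 + ["mature"] * 30

good = np.tile([1.0, 0.0], (60, 1)) + rng.normal(0, 0.2, (60, 2))  # flows rightward
bad = -good                                                        # flows backward
graph = knn_graph(coords, n_neighbors=10)

for name, vel in (("correct flow", good), ("reversed flow", bad)):
    score = cbdir(Embedding(coords, vel, graph), labels, "progenitor", "mature")
    print(f"{name:14s} CBDir(progenitor -> mature) = {score:.3f}")
print("a disconnected pair has no boundary cells and reports a missing score:",
      cbdir(Embedding(coords, good, {i: set() for i in range(60)}),
            labels, "progenitor", "mature"))
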