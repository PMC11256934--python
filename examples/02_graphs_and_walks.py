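"""Build the heterogeneous graph and sample biased random walks.

Two edge sets over the same cells: spatial proximity (distance threshold
on coordinates) and expression similarity (symmetrised kNN over highly
variable genes).  Node2vec-style walks on each graph are the paths the
model convolves over; they are resampled every training epoch.
"""

from pathimpute import build_hetero_graph, normalize, sample_walks, select_hvg
from pathimpute.simulate import make_fixture

data, _ = make_fixture("layered")
norm = normalize(data)
hvg = select_hvg(norm, n_hvg=100)
hetero = build_hetero_graph(norm, hvg, d_thr=None, knn_k=6)  # d_thr=None: auto

for name, g in (("spatial", hetero.spatial), ("gene", hetero.gene)):
    print(f"{name} graph: {g.n_edges} edges, mean degree {g.mean_degree:.2f}")

walks = sample_walks(hetero.spatial, k=8, T=8, q=1.0, p=1.0, seed=0)
print(f"sampled {len(walks.walks)} walks of node-length {walks.k} "
      f"({walks.T} per cell)")
print("one walk from cell 0:", walks.walks[0].tolist())
# Each consecutive pair in a walk is an edge of its graph; position 1 is
# the start cell itself, so every cell contributes its own expression to
# its update.
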