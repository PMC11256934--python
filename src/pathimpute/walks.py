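"""Second-order (node2vec-style) random walk sampling.

Every training epoch the model resamples, for each node of each graph,
T walks of fixed node-length k.  Transitions follow the node2vec scheme:
from the current node, stepping back to the previous node has weight 1/p,
stepping to a common neighbour of current and previous weight 1, and
stepping outward weight 1/q, normalised over the current node's
neighbours.  With p = q = 1 this reduces to a first-order uniform walk
and a fully vectorised sampler is used.

Walk length k counts NODES: a walk of length 8 visits 8 nodes (7 hops),
and position 1 is the start node itself, so every node contributes its
own embedding to its update.  Isolated nodes yield self-padded walks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graphs import CellGraph

logger = logging.getLogger(__name__)

__all__ = ["WalkSet", "sample_walks", "resample_schedule"]


@dataclass
class WalkSet:
    """T sampled walks per start node on one graph.

    ``walks`` has shape (n_nodes * T, k); the T walks of node v occupy
    rows v*T .. (v+1)*T - 1 and each starts at v.
    """

    walks: np.ndarray
    graph_kind: str
    k: int
    T: int
    q: float
    p: float
    seed: int

    @property
    def start_of(self) -> np.ndarray:
        return self.walks[:, 0]

    @property
    def n_nodes(self) -> int:
        return self.walks.shape[0] // self.T

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.walks, fmt="%d", delimiter="\t")


def _sample_uniform(
    indptr: np.ndarray,
    indices: np.ndarray,
    starts: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order uniform walks, vectorised one step at a time."""
    walks = np.empty((len(starts), k), dtype=int)
    walks[:, 0] = starts
    cur = starts.copy()
    deg = np.diff(indptr)
    for t in range(1, k):
        d = deg[cur]
        movable = d > 0
        pick = np.zeros(len(cur), dtype=int)
        if movable.any():
            u = rng.random(int(movable.sum()))
            pick_m = (u * d[movable]).astype(int)
            nxt = indices[indptr[cur[movable]] + pick_m]
            cur = cur.copy()
            cur[movable] = nxt
        walks[:, t] = cur
    return walks


def _step_weights(
    nbrs: np.ndarray, prev: int, prev_nbrs: set, p: float, q: float
) -> np.ndarray:
    w = np.empty(len(nbrs), dtype=float)
    for a, x in enumerate(nbrs):
        if x == prev:
            w[a] = 1.0 / p
        elif x in prev_nbrs:
            w[a] = 1.0
        else:
            w[a] = 1.0 / q
    return w


def _sample_biased(
    graph: CellGraph,
    starts: np.ndarray,
    k: int,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> np.ndarray:
    indptr, indices = graph.adjacency()
    nbr_sets = [set(indices[indptr[v] : indptr[v + 1]].tolist()) for v in range(graph.n_nodes)]
    walks = np.empty((len(starts), k), dtype=int)
    for w, v0 in enumerate(starts):
        walk = [int(v0)]
        for t in range(1, k):
            cur = walk[-1]
            nbrs = indices[indptr[cur] : indptr[cur + 1]]
            if len(nbrs) == 0:
                walk.append(cur)  # isolated: self-padding
                continue
            if t == 1:
                nxt = int(nbrs[rng.integers(len(nbrs))])
            else:
                prev = walk[-2]
                weights = _step_weights(nbrs, prev, nbr_sets[prev], p, q)
                weights /= weights.sum()
                nxt = int(nbrs[rng.choice(len(nbrs), p=weights)])
            walk.append(nxt)
        walks[w] = walk
    return walks


def sample_walks(
    graph: CellGraph,
    k: int,
    T: int,
    q: float = 1.0,
    p: float = 1.0,
    seed: int = 0,
) -> WalkSet:
    """Sample T node2vec walks of node-length k from every node of ``graph``.

    The first transition (no previous node yet) is uniform over the start
    node's neighbours.  Walks are independent and sampled with
    replacement, so duplicates are allowed.  Reproducible given ``seed``.
    """
    if k < 1 or T < 1:
        raise ValueError("k and T must be >= 1")
    if q <= 0 or p <= 0:
        raise ValueError("q and p must be positive")
    rng = np.random.default_rng(seed)
    starts = np.repeat(np.arange(graph.n_nodes), T)
    if (graph.degrees() == 0).any():
        logger.debug(
            "%d isolated node(s); their walks are self-padded",
            int((graph.degrees() == 0).sum()),
        )
    if k == 1:
        walks = starts[:, None].copy()
    elif p == 1.0 and q == 1.0:
        indptr, indices = graph.adjacency()
        walks = _sample_uniform(indptr, indices, starts, k, rng)
    else:
        walks = _sample_biased(graph, starts, k, p, q, rng)
    return WalkSet(walks=walks, graph_kind=graph.kind, k=k, T=T, q=q, p=p, seed=seed)


def resample_schedule(epoch: int, base_seed: int, stream: int = 0) -> int:
    """Deterministic per-epoch walk seed.

    Maps (epoch, base_seed, stream) through a SeedSequence so that full
    training runs are reproducible from one base seed while every epoch
    (and every graph, via ``stream``) draws fresh walks.
    """
    ss = np.random.SeedSequence([int(base_seed), int(epoch), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))
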