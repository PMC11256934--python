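"""Biased second-order walk sampling and the per-epoch seed schedule."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from pathimpute.graphs import CellGraph
from pathimpute.walks import resample_schedule, sample_walks


def graph_from_edges(n, edges):
    return CellGraph(n_nodes=n, edges=np.asarray(edges, dtype=int), kind="spatial")


def exact_walk_distribution(graph, start, k, p, q):
    """Independent oracle: enumerate all walks of node-length k with their
    probabilities under the second-order transition rule (first step
    uniform; then weight 1/p to return, 1 to a common neighbour of the
    previous node, 1/q outward)."""
    nbrs = {v: set(graph.neighbors(v).tolist()) for v in range(graph.n_nodes)}
    dist = {}

    def recurse(walk, prob):
        if len(walk) == k:
            dist[tuple(walk)] = dist.get(tuple(walk), 0.0) + prob
            return
        cur = walk[-1]
        options = sorted(nbrs[cur])
        if not options:
            recurse(walk + [cur], prob)
            return
        if len(walk) == 1:
            for x in options:
                recurse(walk + [x], prob / len(options))
        else:
            prev = walk[-2]
            weights = []
            for x in options:
                if x == prev:
                    weights.append(1.0 / p)
                elif x in nbrs[prev]:
                    weights.append(1.0)
                else:
                    weights.append(1.0 / q)
            total = sum(weights)
            for x, w in zip(options, weights):
                recurse(walk + [x], prob * w / total)

    recurse([start], 1.0)
    return dist


def test_walks_start_at_their_node_and_cover_all_nodes():
    g = graph_from_edges(5, [[0, 1], [1, 2], [2, 3], [3, 4], [4, 0]])
    ws = sample_walks(g, k=4, T=3, seed=0)
    assert ws.walks.shape == (15, 4)
    starts, counts = np.unique(ws.start_of, return_counts=True)
    assert np.array_equal(starts, np.arange(5)) and (counts == 3).all()


@pytest.mark.parametrize("q,p", [(1.0, 1.0), (2.5, 0.5)])
def test_every_step_is_an_edge(q, p, rng):
    coords = rng.uniform(0, 1, (25, 2))
    from pathimpute.graphs import build_spatial_graph

    g = build_spatial_graph(coords, d_thr=0.35)
    ws = sample_walks(g, k=5, T=2, q=q, p=p, seed=3)
    edges = {tuple(e) for e in g.edges}
    for walk in ws.walks:
        for a, b in zip(walk[:-1], walk[1:]):
            if a == b:  # padding at a dead end / isolated node
                assert len(g.neighbors(a)) == 0
            else:
                assert (min(a, b), max(a, b)) in edges


def test_k1_walks_are_just_start_nodes():
    g = graph_from_edges(4, [[0, 1], [2, 3]])
    ws = sample_walks(g, k=1, T=2, seed=0)
    assert np.array_equal(ws.walks[:, 0], ws.start_of)
    assert ws.walks.shape == (8, 1)


def test_isolated_node_self_padding():
    g = graph_from_edges(3, [[0, 1]])
    ws = sample_walks(g, k=4, T=2, seed=1)
    iso = ws.walks[ws.start_of == 2]
    assert (iso == 2).all()


def test_strong_inward_bias_suppresses_outward_moves():
    # on the path 0-1-2, from start 0 the third node is either 0 (return,
    # weight 1/p) or 2 (outward, weight 1/q); large q kills [0, 1, 2]
    g = graph_from_edges(3, [[0, 1], [1, 2]])
    ws = sample_walks(g, k=3, T=400, q=1e6, p=1.0, seed=2)
    from0 = ws.walks[ws.start_of == 0]
    frac_outward = np.mean([tuple(w) == (0, 1, 2) for w in from0])
    assert frac_outward < 0.01


def test_uniform_one_step_distribution_chi_square():
    # q = p = 1 must reduce to a first-order uniform walk
    g = graph_from_edges(5, [[0, 1], [0, 2], [0, 3], [0, 4], [1, 2], [3, 4]])
    ws = sample_walks(g, k=2, T=10_000, seed=5)
    steps = ws.walks[ws.start_of == 0][:, 1]
    counts = np.bincount(steps, minlength=5)[1:]
    assert chisquare(counts).pvalue > 1e-3


def test_triangle_second_order_frequencies_match_exact_chain():
    g = graph_from_edges(3, [[0, 1], [1, 2], [0, 2]])
    n_samples = 100_000
    ws = sample_walks(g, k=3, T=n_samples // 3, seed=11)
    from0 = ws.walks[ws.start_of == 0]
    n0 = len(from0)
    exact = exact_walk_distribution(g, 0, 3, p=1.0, q=1.0)
    observed = {}
    for w in map(tuple, from0):
        observed[w] = observed.get(w, 0) + 1
    assert set(observed) <= set(exact)
    for walk, prob in exact.items():
        se = np.sqrt(prob * (1 - prob) / n0)
        assert abs(observed.get(walk, 0) / n0 - prob) <= 3 * se + 1e-12


def test_biased_walk_frequencies_match_enumeration_oracle():
    # square with one diagonal: return / common-neighbour / outward all occur
    g = graph_from_edges(4, [[0, 1], [1, 2], [2, 3], [3, 0], [0, 2]])
    p, q = 0.5, 2.0
    ws = sample_walks(g, k=4, T=5000, q=q, p=p, seed=13)
    from0 = ws.walks[ws.start_of == 0]
    n0 = len(from0)
    exact = exact_walk_distribution(g, 0, 4, p=p, q=q)
    observed = {}
    for w in map(tuple, from0):
        observed[w] = observed.get(w, 0) + 1
    assert set(observed) <= set(exact)
    for walk, prob in sorted(exact.items()):
        se = np.sqrt(prob * (1 - prob) / n0)
        assert abs(observed.get(walk, 0) / n0 - prob) <= 4 * se + 1e-12


def test_resample_schedule_contract():
    assert resample_schedule(5, 123) == resample_schedule(5, 123)
    seeds = [resample_schedule(e, 42) for e in range(100)]
    assert len(set(seeds)) == 100
    other = [resample_schedule(e, 43) for e in range(100)]
    assert not set(seeds) & set(other)
    assert all(0 <= s < 2**31 for s in seeds)
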