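"""Spatial threshold graph and gene-similarity kNN graph construction."""

import numpy as np
import pytest

from pathimpute.graphs import (
    CellGraph,
    HeteroGraph,
    auto_distance_threshold,
    build_gene_graph,
    build_hetero_graph,
    build_spatial_graph,
    knn_neighbor_lists,
    load_graph,
    save_graph,
)
from pathimpute.io import select_hvg
from pathimpute.simulate import make_fixture


def edge_set(graph: CellGraph) -> set:
    return {tuple(e) for e in graph.edges}


# ---------------------------------------------------------------------------
# spatial graph
# ---------------------------------------------------------------------------

def test_spatial_threshold_forced_example():
    g = build_spatial_graph(np.array([[0, 0], [0, 1], [5, 5]]), d_thr=2)
    assert edge_set(g) == {(0, 1)}


def test_spatial_threshold_below_min_distance_is_empty():
    g = build_spatial_graph(np.array([[0, 0], [0, 1], [5, 5]]), d_thr=0.5)
    assert g.n_edges == 0


def test_spatial_single_node_no_error():
    g = build_spatial_graph(np.array([[1.0, 2.0]]), d_thr=1)
    assert g.n_edges == 0 and g.n_nodes == 1


def test_spatial_matches_bruteforce_oracle(rng):
    coords = rng.uniform(0, 1, (40, 2))
    g = build_spatial_graph(coords, d_thr=0.3)
    brute = {
        (i, j)
        for i in range(40)
        for j in range(i + 1, 40)
        if np.linalg.norm(coords[i] - coords[j]) <= 0.3
    }
    assert edge_set(g) == brute


def test_spatial_invariant_under_rigid_motion(rng):
    coords = rng.uniform(0, 5, (60, 2))
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = coords @ rot.T + np.array([13.0, -4.0])
    assert edge_set(build_spatial_graph(coords, 0.8)) == edge_set(
        build_spatial_graph(moved, 0.8)
    )


def test_no_self_loops_or_duplicates_enforced():
    with pytest.raises(ValueError, match="self-loop"):
        CellGraph(n_nodes=3, edges=np.array([[1, 1]]), kind="spatial")
    g = CellGraph(n_nodes=3, edges=np.array([[0, 1], [1, 0], [0, 1]]), kind="spatial")
    assert g.n_edges == 1


# ---------------------------------------------------------------------------
# gene graph
# ---------------------------------------------------------------------------

def test_gene_knn_forced_example():
    x = np.array([[0.0, 0.0], [0.0, 0.1], [9.0, 9.0]])
    g = build_gene_graph(x, knn_k=1)
    # 0<->1 mutually nearest; 2's nearest is 1 (tie-free)
    assert edge_set(g) == {(0, 1), (1, 2)}
    assert np.array_equal(g.knn, [[1], [0], [1]])


def test_gene_knn_saturation_gives_complete_graph(rng):
    x = rng.normal(size=(7, 3))
    g = build_gene_graph(x, knn_k=6)
    assert g.n_edges == 7 * 6 // 2


def test_gene_knn_matches_bruteforce_oracle(rng):
    x = rng.normal(size=(30, 8))
    nbrs = knn_neighbor_lists(x, 4)
    for i in range(30):
        d = np.linalg.norm(x - x[i], axis=1)
        d[i] = np.inf
        expected = sorted(range(30), key=lambda j: (d[j], j))[:4]
        assert list(nbrs[i]) == expected


def test_gene_knn_ties_broken_by_index():
    # three identical cells: everyone's nearest neighbour is the lowest index
    x = np.zeros((3, 4))
    nbrs = knn_neighbor_lists(x, 1)
    assert np.array_equal(nbrs, [[1], [0], [0]])


def test_gene_graph_invariant_under_gene_permutation(rng):
    x = rng.normal(size=(25, 10))
    perm = rng.permutation(10)
    a = build_gene_graph(x, knn_k=3)
    b = build_gene_graph(x[:, perm], knn_k=3)
    assert edge_set(a) == edge_set(b)


# ---------------------------------------------------------------------------
# hetero graph
# ---------------------------------------------------------------------------

def test_hetero_on_lattice_has_hex_like_spatial_degree(tiny):
    data, _ = tiny
    hvg = select_hvg(data, n_hvg=10)
    hg = build_hetero_graph(data, hvg, d_thr=1.5, knn_k=3)  # 1.5 x unit pitch
    assert 4.0 <= hg.spatial.mean_degree <= 8.0


def test_hetero_degenerate_identical_expression(tiny):
    data, _ = tiny
    flat = data.copy()
    flat.values = np.ones((data.n_cells, data.n_genes))
    hvg = select_hvg(flat, n_hvg=5)
    hg = build_hetero_graph(flat, hvg, d_thr=1.5, knn_k=4)
    # tie rule makes the kNN relation well-defined: k lowest indices
    assert np.array_equal(hg.gene.knn[5], [0, 1, 2, 3])


def test_hetero_edge_sets_are_independent(rng):
    coords = rng.uniform(0, 10, (20, 2))
    x = rng.normal(size=(20, 6))
    from pathimpute.io import ExpressionDataset

    data = ExpressionDataset(
        values=np.abs(x), cell_ids=[f"c{i}" for i in range(20)],
        gene_ids=[f"g{j}" for j in range(6)], coords=coords,
    )
    hg = build_hetero_graph(data, select_hvg(data, 6), d_thr=1e-9, knn_k=1)
    assert hg.spatial.n_edges == 0 and hg.gene.n_edges > 0


def test_hetero_node_count_mismatch_rejected():
    a = CellGraph(n_nodes=3, edges=np.empty((0, 2), int), kind="spatial")
    b = CellGraph(n_nodes=4, edges=np.empty((0, 2), int), kind="gene")
    with pytest.raises(ValueError):
        HeteroGraph(spatial=a, gene=b)


def test_auto_threshold_reaches_target_degree(tiny):
    data, _ = tiny
    d = auto_distance_threshold(data.coords, target_mean_degree=6.0)
    assert build_spatial_graph(data.coords, d).mean_degree >= 6.0
    # minimality: shaving the threshold drops below target
    assert build_spatial_graph(data.coords, d - 1e-9).mean_degree < 6.0


def test_graph_tsv_roundtrip(tmp_path, rng):
    coords = rng.uniform(0, 3, (15, 2))
    g = build_spatial_graph(coords, d_thr=1.0)
    save_graph(g, tmp_path / "g.tsv")
    back = load_graph(tmp_path / "g.tsv")
    assert back.n_nodes == g.n_nodes and back.kind == g.kind
    assert np.array_equal(back.edges, g.edges)
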