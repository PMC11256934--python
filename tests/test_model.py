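"""Path convolution, layer combine, full forward pass, parameter counts
and the analytic-gradient check."""

import numpy as np
import pytest

from pathimpute.graphs import build_spatial_graph
from pathimpute.model import (
    ModelConfig,
    PathGNN,
    count_parameters,
    layer_forward,
    path_convolve,
    path_convolve_backward,
)
from pathimpute.training import masked_mse_loss, _masked_mse_grad
from pathimpute.walks import WalkSet, sample_walks


def make_walks(walks_array, T, kind="spatial"):
    walks_array = np.asarray(walks_array, dtype=int)
    return WalkSet(
        walks=walks_array, graph_kind=kind, k=walks_array.shape[1], T=T,
        q=1.0, p=1.0, seed=0,
    )


def random_instance(rng, n=6, d=4, k=3, T=2):
    coords = rng.uniform(0, 1, (n, 2))
    g = build_spatial_graph(coords, d_thr=0.8)
    walks = sample_walks(g, k=k, T=T, seed=int(rng.integers(1000)))
    f = rng.normal(size=(n, d))
    return g, walks, f


def convolve_oracle(op, walks, f):
    """Naive triple loop over (node, path, position)."""
    op = np.asarray(op, dtype=float)
    if op.ndim == 1:
        op = op[:, None]
    n, T, k = walks.n_nodes, walks.T, walks.k
    d = f.shape[1]
    out = np.zeros((n, d))
    for v in range(n):
        for t in range(T):
            walk = walks.walks[v * T + t]
            for i in range(k):
                for j in range(d):
                    w = op[i, 0] if op.shape[1] == 1 else op[i, j]
                    out[v, j] += w * f[walk[i], j] / T
    return out


# ---------------------------------------------------------------------------
# path convolution
# ---------------------------------------------------------------------------

def test_zero_operator_annihilates(rng):
    _, walks, f = random_instance(rng)
    assert not path_convolve(np.zeros((walks.k, f.shape[1])), walks, f).any()


def test_k1_all_ones_operator_is_identity(rng):
    f = rng.normal(size=(5, 3))
    walks = make_walks(np.arange(5)[:, None], T=1)
    assert np.allclose(path_convolve(np.ones((1, 3)), walks, f), f)


@pytest.mark.parametrize("channel_shared", [False, True])
def test_convolution_matches_triple_loop_oracle(rng, channel_shared):
    _, walks, f = random_instance(rng, n=6, d=4, k=3, T=2)
    op = rng.normal(size=(3, 1) if channel_shared else (3, 4))
    assert np.allclose(path_convolve(op, walks, f), convolve_oracle(op, walks, f), atol=1e-6)


def test_convolution_is_bilinear(rng):
    _, walks, f1 = random_instance(rng, d=4)
    f2 = rng.normal(size=f1.shape)
    op1 = rng.normal(size=(walks.k, 4))
    op2 = rng.normal(size=(walks.k, 4))
    a, b = 1.7, -0.4
    assert np.allclose(
        path_convolve(op1, walks, a * f1 + b * f2),
        a * path_convolve(op1, walks, f1) + b * path_convolve(op1, walks, f2),
    )
    assert np.allclose(
        path_convolve(a * op1 + b * op2, walks, f1),
        a * path_convolve(op1, walks, f1) + b * path_convolve(op2, walks, f1),
    )


def test_convolution_permutation_equivariance(rng):
    n, d = 6, 3
    _, walks, f = random_instance(rng, n=n, d=d, k=3, T=2)
    op = rng.normal(size=(3, d))
    perm = rng.permutation(n)
    inv = np.argsort(perm)
    # relabel node v -> perm[v] everywhere, then reorder walk rows so the
    # block of node perm[v] holds its own walks
    order = np.argsort(perm[np.repeat(np.arange(n), walks.T)], kind="stable")
    walks_p = make_walks(perm[walks.walks][order], T=walks.T)
    f_p = f[inv]
    out = path_convolve(op, walks, f)
    out_p = path_convolve(op, walks_p, f_p)
    assert np.allclose(out_p, out[inv])


def test_operator_shape_mismatch_reported(rng):
    _, walks, f = random_instance(rng, d=4, k=3)
    with pytest.raises(ValueError, match="path length"):
        path_convolve(np.ones((walks.k + 1, 4)), walks, f)
    with pytest.raises(ValueError, match="incompatible"):
        path_convolve(np.ones((walks.k, 2)), walks, f)


def test_convolve_backward_matches_finite_difference(rng):
    _, walks, f = random_instance(rng, n=6, d=3, k=3, T=2)
    op = rng.normal(size=(3, 3))
    grad_out = rng.normal(size=f.shape)
    g_op, g_f = path_convolve_backward(op, walks, f, grad_out)
    eps = 1e-6
    for idx in [(0, 0), (1, 2), (2, 1)]:
        op2 = op.copy()
        op2[idx] += eps
        num = ((path_convolve(op2, walks, f) - path_convolve(op, walks, f)) * grad_out).sum() / eps
        assert abs(num - g_op[idx]) < 1e-5


# ---------------------------------------------------------------------------
# layer combine
# ---------------------------------------------------------------------------

def test_layer_zero_weight_annihilates(rng):
    _, walks, f = random_instance(rng, d=4)
    d = 4
    out = layer_forward(
        np.ones((walks.k, d)), np.ones((walks.k, d)),
        np.zeros((2 * d, d)), np.zeros(d), walks, walks, f,
    )
    assert not out.any()


def test_layer_zero_input_gives_relu_bias(rng):
    _, walks, _ = random_instance(rng, d=4)
    d = 4
    bias = np.array([1.0, -2.0, 0.5, -0.1])
    out = layer_forward(
        np.ones((walks.k, d)), np.ones((walks.k, d)),
        rng.normal(size=(2 * d, d)), bias, walks, walks, np.zeros((walks.n_nodes, d)),
    )
    assert np.allclose(out, np.tile(np.maximum(bias, 0), (walks.n_nodes, 1)))


def test_layer_matches_compositional_oracle(rng):
    _, walks_s, f = random_instance(rng, d=4)
    _, walks_g, _ = random_instance(rng, d=4)
    d = 4
    op_s = rng.normal(size=(walks_s.k, d))
    op_g = rng.normal(size=(walks_g.k, d))
    W1 = rng.normal(size=(2 * d, d))
    b = rng.normal(size=d)
    out = layer_forward(op_s, op_g, W1, b, walks_s, walks_g, f)
    hs = convolve_oracle(op_s, walks_s, f)
    hg = convolve_oracle(op_g, walks_g, f)
    expected = np.maximum(np.concatenate([hs, hg], axis=1) @ W1 + b, 0)
    assert np.allclose(out, expected, atol=1e-10)


def test_degenerate_layer_is_dense_layer_on_duplicated_input(rng):
    # k = 1, T = 1, op = 1: the convolution is the identity, so the layer
    # is a plain dense layer on [f, f]
    n, d = 5, 3
    f = rng.normal(size=(n, d))
    walks = make_walks(np.arange(n)[:, None], T=1)
    W1 = rng.normal(size=(2 * d, d))
    b = rng.normal(size=d)
    out = layer_forward(np.ones((1, d)), np.ones((1, d)), W1, b, walks, walks, f)
    assert np.allclose(out, np.maximum(np.hstack([f, f]) @ W1 + b, 0))


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def small_model_instance(rng, n=6, m=5, L=2, d=4, seed=0):
    coords = rng.uniform(0, 1, (n, 2))
    g = build_spatial_graph(coords, d_thr=0.9)
    cfg = ModelConfig(L=L, d_emb=d, k_s=3, k_g=3, T_s=2, T_g=2, seed=seed)
    model = PathGNN(cfg, m)
    ws = sample_walks(g, k=3, T=2, seed=1)
    wg = sample_walks(g, k=3, T=2, seed=2)
    X = np.abs(rng.normal(size=(n, m)))
    return model, X, ws, wg


def test_zeroed_decoder_gives_zero_matrix(rng):
    model, X, ws, wg = small_model_instance(rng)
    model.params["dec_W2"][:] = 0
    model.params["dec_b2"][:] = 0
    assert not model.forward(X, ws, wg).any()


def test_forward_is_deterministic_given_walks(rng):
    model, X, ws, wg = small_model_instance(rng, n=5, m=7)
    a = model.forward(X, ws, wg)
    b = model.forward(X, ws, wg)
    assert np.array_equal(a, b)


def test_forward_rejects_non_finite_input(rng):
    model, X, ws, wg = small_model_instance(rng)
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        model.forward(X, ws, wg)


def test_single_layer_model_matches_hand_chained_oracle(rng):
    model, X, ws, wg = small_model_instance(rng, n=6, m=4, L=1, d=3)
    P = model.params
    f0 = X @ P["enc_W"] + P["enc_b"]
    hs = convolve_oracle(P["op_s_l0"], ws, f0)
    hg = convolve_oracle(P["op_g_l0"], wg, f0)
    f1 = np.maximum(np.concatenate([hs, hg], axis=1) @ P["W1_l0"] + P["b1_l0"], 0)
    h = np.maximum(f1 @ P["dec_W1"] + P["dec_b1"], 0)
    expected = h @ P["dec_W2"] + P["dec_b2"]
    assert np.allclose(model.forward(X, ws, wg), expected, atol=1e-5)


def test_model_gradients_match_finite_differences(rng):
    """Analytic reverse-mode gradients of the masked loss vs central
    finite differences, every parameter tensor sampled."""
    model, X, ws, wg = small_model_instance(rng, n=6, m=5, L=2, d=4, seed=3)
    idx = np.array([[0, 1], [2, 3], [4, 0], [5, 2]])
    target = np.abs(rng.normal(size=X.shape)) + 0.5

    def loss():
        return masked_mse_loss(model.forward(X, ws, wg), target, idx)

    X_hat, cache = model.forward(X, ws, wg, return_cache=True)
    grads = model.backward(cache, _masked_mse_grad(X_hat, target, idx))
    eps = 1e-6
    rng_local = np.random.default_rng(0)
    for name, arr in model.params.items():
        flat = arr.reshape(-1)
        for pos in rng_local.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[pos]
            flat[pos] = orig + eps
            up = loss()
            flat[pos] = orig - eps
            down = loss()
            flat[pos] = orig
            num = (up - down) / (2 * eps)
            ana = grads[name].reshape(-1)[pos]
            denom = max(abs(num), abs(ana), 1e-8)
            assert abs(num - ana) / denom < 1e-4, f"{name}[{pos}]: {num} vs {ana}"


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def test_operator_params_channel_distinct_formula():
    cfg = ModelConfig(L=1, d_emb=64, k_s=8, k_g=8, share_mode="op_ind")
    assert count_parameters(cfg, m=100)["operators"] == (8 + 8) * 64  # 1024


def test_globally_shared_operators_independent_of_depth():
    counts = {
        L: count_parameters(ModelConfig(L=L, share_mode="op_glo"), m=50)["operators"]
        for L in (1, 3, 6)
    }
    assert len(set(counts.values())) == 1


@pytest.mark.parametrize("mode", ["op_glo", "op_cha", "op_lay", "op_ind"])
def test_counts_match_parameter_registry_enumeration(mode):
    cfg = ModelConfig(L=3, d_emb=8, k_s=4, k_g=5, T_s=2, T_g=2, share_mode=mode)
    model = PathGNN(cfg, n_genes=11)
    assert count_parameters(cfg, 11) == model.parameter_count()


def test_share_mode_ordering():
    cfgs = {
        mode: count_parameters(
            ModelConfig(L=3, d_emb=16, share_mode=mode), m=40
        )["operators"]
        for mode in ("op_glo", "op_cha", "op_lay", "op_ind")
    }
    assert cfgs["op_glo"] <= cfgs["op_cha"] <= cfgs["op_lay"] <= cfgs["op_ind"]
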