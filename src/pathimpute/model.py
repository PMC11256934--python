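"""The path-operator graph network.

Each layer holds one learnable path operator per graph: a weight per walk
position (and, in the channel-distinct sharing modes, per embedding
channel).  A node's update convolves the embeddings of the nodes visited
by its sampled walks against the operator and averages over the T walks:

    conv(v)[j] = (1/T) * sum_{walks P from v} sum_{i=1..k} op[i, j] * f[P_i, j]

The spatial and gene-graph convolutions are concatenated, passed through
a learned linear map and ReLU (the layer combine), and after L layers a
small MLP decoder maps embeddings back to gene space.  The convolution is
channel-wise: each embedding channel j is convolved with its own operator
column, which is what per-channel operator sharing modes require.

Four operator sharing modes control how operators are tied:

====== ======================= =========================
mode    across layers           across channels
====== ======================= =========================
op_glo  one shared operator     one scalar per position
op_cha  distinct per layer      one scalar per position
op_lay  one shared operator     distinct per channel
op_ind  distinct per layer      distinct per channel
====== ======================= =========================

Gradients are computed by hand-derived reverse-mode differentiation (the
whole network is a short chain of gathers, products and affine maps), so
the package has no deep-learning framework dependency and runs CPU-only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .walks import WalkSet

__all__ = [
    "ModelConfig",
    "PathGNN",
    "path_convolve",
    "path_convolve_backward",
    "layer_forward",
    "count_parameters",
    "SHARE_MODES",
]

SHARE_MODES = ("op_glo", "op_cha", "op_lay", "op_ind")
MODALITIES = ("both", "spatial", "gene")


@dataclass
class ModelConfig:
    """Model hyper-parameters; defaults are the recommended settings
    (4 layers, path length 8 on both graphs, 8 walks per node, unbiased
    walks, embedding width 64)."""

    L: int = 4
    d_emb: int = 64
    k_s: int = 8
    k_g: int = 8
    T_s: int = 8
    T_g: int = 8
    q_s: float = 1.0
    q_g: float = 1.0
    p: float = 1.0
    share_mode: str = "op_ind"
    raw_features: bool = False
    modality: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("L", "d_emb", "k_s", "k_g", "T_s", "T_g"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.q_s <= 0 or self.q_g <= 0 or self.p <= 0:
            raise ValueError("walk biases must be positive")
        if self.share_mode not in SHARE_MODES:
            raise ValueError(f"share_mode must be one of {SHARE_MODES}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")


# ---------------------------------------------------------------------------
# Path convolution (functional core)
# ---------------------------------------------------------------------------

def _as_op2d(op: np.ndarray, d: int) -> np.ndarray:
    """Validate an operator against embedding width d; returns (k, 1|d)."""
    op = np.asarray(op, dtype=float)
    if op.ndim == 1:
        op = op[:, None]
    if op.ndim != 2 or op.shape[1] not in (1, d):
        raise ValueError(
            f"operator shape {op.shape} incompatible with embedding width {d} "
            f"(expected (k,), (k, 1) or (k, {d}))"
        )
    return op


def path_convolve(op: np.ndarray, walks: WalkSet, f: np.ndarray) -> np.ndarray:
    """Convolve node embeddings along sampled walks.

    ``op`` has shape (k, d) (channel-distinct) or (k,) / (k, 1)
    (channel-shared, broadcast across channels); ``f`` is (n, d).  Output
    row v is the average over v's T walks of sum_i op_i * f[P_i], taken
    channel-wise.
    """
    f = np.asarray(f, dtype=float)
    op = _as_op2d(op, f.shape[1])
    if op.shape[0] != walks.k:
        raise ValueError(
            f"operator path length {op.shape[0]} != walk length {walks.k}"
        )
    n, T = walks.n_nodes, walks.T
    gathered = f[walks.walks]                       # (n*T, k, d)
    contrib = np.einsum("wkd,kd->wd", gathered, np.broadcast_to(op, (walks.k, f.shape[1])))
    return contrib.reshape(n, T, f.shape[1]).mean(axis=1)


def path_convolve_backward(
    op: np.ndarray,
    walks: WalkSet,
    f: np.ndarray,
    grad_out: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of ``path_convolve`` w.r.t. the operator and the embeddings.

    Returns (grad_op, grad_f); grad_op matches the storage shape of
    ``op`` (channel-shared operators receive the channel-summed gradient).
    """
    f = np.asarray(f, dtype=float)
    d = f.shape[1]
    op2 = _as_op2d(op, d)
    shared = op2.shape[1] == 1
    gw = np.repeat(grad_out / walks.T, walks.T, axis=0)      # (n*T, d)
    full_op = np.broadcast_to(op2, (walks.k, d))
    grad_gathered = full_op[None, :, :] * gw[:, None, :]     # (n*T, k, d)
    grad_f = np.zeros_like(f)
    np.add.at(grad_f, walks.walks.ravel(), grad_gathered.reshape(-1, d))
    gathered = f[walks.walks]
    grad_full = np.einsum("wkd,wd->kd", gathered, gw)
    if shared:
        grad_op = grad_full.sum(axis=1, keepdims=True)
        if np.asarray(op).ndim == 1:
            grad_op = grad_op.ravel()
    else:
        grad_op = grad_full
    return grad_op, grad_f


def layer_forward(
    op_s: np.ndarray,
    op_g: np.ndarray,
    W1: np.ndarray,
    bias: np.ndarray,
    walks_s: WalkSet,
    walks_g: WalkSet,
    f: np.ndarray,
    modality: str = "both",
) -> np.ndarray:
    """One combine layer: ReLU(W1 . [spatial conv, gene conv] + bias).

    ``W1`` is stored as (2*d_in, d_out) so the combine is
    ``concat @ W1 + bias``.  In single-modality variants the active
    branch's convolution fills both halves of the concatenation.
    """
    hs = path_convolve(op_s, walks_s, f) if modality in ("both", "spatial") else None
    hg = path_convolve(op_g, walks_g, f) if modality in ("both", "gene") else None
    if modality == "spatial":
        hg = hs
    elif modality == "gene":
        hs = hg
    z = np.concatenate([hs, hg], axis=1) @ W1 + bias
    return np.maximum(z, 0.0)


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def count_parameters(config: ModelConfig, m: int) -> dict[str, int]:
    """Exact parameter counts {operators, combine, encoder, decoder, total}.

    Channel-distinct modes (op_ind, op_lay) cost (k_s + k_g) * d_emb
    operator weights per layer; channel-shared modes (op_glo, op_cha)
    cost k_s + k_g.  Layer-shared modes (op_glo, op_lay) pay that cost
    once instead of once per layer.
    """
    d = m if config.raw_features else config.d_emb
    width = d if config.share_mode in ("op_ind", "op_lay") else 1
    per_layer = (config.k_s + config.k_g) * width
    layer_factor = config.L if config.share_mode in ("op_ind", "op_cha") else 1
    operators = per_layer * layer_factor
    combine = config.L * (2 * d * d + d)
    encoder = 0 if config.raw_features else m * d + d
    decoder = d * d + d + d * m + m
    return {
        "operators": operators,
        "combine": combine,
        "encoder": encoder,
        "decoder": decoder,
        "total": operators + combine + encoder + decoder,
    }


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class PathGNN:
    """L path-convolution layers plus a linear encoder and MLP decoder.

    Parameters live in ``self.params`` (name -> float64 array); sharing
    modes are realised by layers referencing the same parameter name, so
    enumerating ``self.params`` counts each shared tensor exactly once.
    """

    def __init__(self, config: ModelConfig, n_genes: int):
        self.config = config
        self.n_genes = n_genes
        self.d = n_genes if config.raw_features else config.d_emb
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- parameter registry -------------------------------------------------
    def op_name(self, graph: str, layer: int) -> str:
        if self.config.share_mode in ("op_glo", "op_lay"):
            return f"op_{graph}"
        return f"op_{graph}_l{layer}"

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg, d, m = self.config, self.d, self.n_genes
        width = d if cfg.share_mode in ("op_ind", "op_lay") else 1

        def glorot(fan_in: int, fan_out: int, shape) -> np.ndarray:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        if not cfg.raw_features:
            self.params["enc_W"] = glorot(m, d, (m, d))
            self.params["enc_b"] = np.zeros(d)
        for layer in range(cfg.L):
            for graph, k in (("s", cfg.k_s), ("g", cfg.k_g)):
                name = self.op_name(graph, layer)
                if name not in self.params:
                    # near 1/k so the initial convolution is close to a path mean
                    self.params[name] = (1.0 + rng.uniform(-0.1, 0.1, (k, width))) / k
            self.params[f"W1_l{layer}"] = glorot(2 * d, d, (2 * d, d))
            self.params[f"b1_l{layer}"] = np.zeros(d)
        self.params["dec_W1"] = glorot(d, d, (d, d))
        self.params["dec_b1"] = np.zeros(d)
        self.params["dec_W2"] = glorot(d, m, (d, m))
        self.params["dec_b2"] = np.zeros(m)

    def parameter_count(self) -> dict[str, int]:
        """Enumerate the live registry (shared tensors counted once)."""
        groups = {"operators": 0, "combine": 0, "encoder": 0, "decoder": 0}
        for name, arr in self.params.items():
            if name.startswith("op_"):
                groups["operators"] += arr.size
            elif name.startswith(("W1_", "b1_")):
                groups["combine"] += arr.size
            elif name.startswith("enc_"):
                groups["encoder"] += arr.size
            else:
                groups["decoder"] += arr.size
        groups["total"] = sum(groups.values())
        return groups

    # -- forward / backward -------------------------------------------------
    def forward(
        self,
        X_obs: np.ndarray,
        walks_s: WalkSet,
        walks_g: WalkSet,
        return_cache: bool = False,
    ):
        """Impute: encoder -> L path-convolution layers -> decoder.

        Deterministic given the walk sets.  Raises on non-finite input
        before any layer runs.
        """
        X_obs = np.asarray(X_obs, dtype=float)
        if not np.isfinite(X_obs).all():
            raise ValueError("input matrix contains NaN or Inf")
        cfg, P = self.config, self.params
        cache: dict = {"X_obs": X_obs, "layers": []}
        if cfg.raw_features:
            f = X_obs
        else:
            f = X_obs @ P["enc_W"] + P["enc_b"]
        for layer in range(cfg.L):
            op_s = P[self.op_name("s", layer)]
            op_g = P[self.op_name("g", layer)]
            hs = hg = None
            if cfg.modality in ("both", "spatial"):
                hs = path_convolve(op_s, walks_s, f)
            if cfg.modality in ("both", "gene"):
                hg = path_convolve(op_g, walks_g, f)
            left, right = {
                "both": (hs, hg),
                "spatial": (hs, hs),
                "gene": (hg, hg),
            }[cfg.modality]
            z = np.concatenate([left, right], axis=1) @ P[f"W1_l{layer}"] + P[f"b1_l{layer}"]
            f_new = np.maximum(z, 0.0)
            cache["layers"].append({"f_in": f, "z": z})
            f = f_new
        cache["f_L"] = f
        h = np.maximum(f @ P["dec_W1"] + P["dec_b1"], 0.0)
        cache["dec_h"] = h
        X_hat = h @ P["dec_W2"] + P["dec_b2"]
        if return_cache:
            cache["walks_s"], cache["walks_g"] = walks_s, walks_g
            return X_hat, cache
        return X_hat

    def backward(self, cache: dict, grad_Xhat: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter, given
        dLoss/dX_hat.  Shared operators accumulate across layers."""
        cfg, P = self.config, self.params
        walks_s, walks_g = cache["walks_s"], cache["walks_g"]
        grads = {name: np.zeros_like(arr) for name, arr in P.items()}

        h = cache["dec_h"]
        grads["dec_W2"] = cache["dec_h"].T @ grad_Xhat
        grads["dec_b2"] = grad_Xhat.sum(axis=0)
        gh = grad_Xhat @ P["dec_W2"].T
        gz = gh * (h > 0)
        grads["dec_W1"] = cache["f_L"].T @ gz
        grads["dec_b1"] = gz.sum(axis=0)
        gf = gz @ P["dec_W1"].T

        d = self.d
        for layer in reversed(range(cfg.L)):
            lc = cache["layers"][layer]
            f_in, z = lc["f_in"], lc["z"]
            gz = gf * (z > 0)
            op_s = P[self.op_name("s", layer)]
            op_g = P[self.op_name("g", layer)]
            # recompute the convolutions needed for the combine gradient
            hs = hg = None
            if cfg.modality in ("both", "spatial"):
                hs = path_convolve(op_s, walks_s, f_in)
            if cfg.modality in ("both", "gene"):
                hg = path_convolve(op_g, walks_g, f_in)
            left, right = {
                "both": (hs, hg),
                "spatial": (hs, hs),
                "gene": (hg, hg),
            }[cfg.modality]
            concat = np.concatenate([left, right], axis=1)
            grads[f"W1_l{layer}"] += concat.T @ gz
            grads[f"b1_l{layer}"] += gz.sum(axis=0)
            gconcat = gz @ P[f"W1_l{layer}"].T
            g_left, g_right = gconcat[:, :d], gconcat[:, d:]
            if cfg.modality == "both":
                g_hs, g_hg = g_left, g_right
            elif cfg.modality == "spatial":
                g_hs, g_hg = g_left + g_right, None
            else:
                g_hs, g_hg = None, g_left + g_right
            gf = np.zeros_like(f_in)
            if g_hs is not None:
                g_op, g_f = path_convolve_backward(op_s, walks_s, f_in, g_hs)
                grads[self.op_name("s", layer)] += g_op
                gf += g_f
            if g_hg is not None:
                g_op, g_f = path_convolve_backward(op_g, walks_g, f_in, g_hg)
                grads[self.op_name("g", layer)] += g_op
                gf += g_f
        if not cfg.raw_features:
            grads["enc_W"] = cache["X_obs"].T @ gf
            grads["enc_b"] = gf.sum(axis=0)
        return grads

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.params)
        path.with_suffix(".json").write_text(
            json.dumps({"config": asdict(self.config), "n_genes": self.n_genes})
        )

    @classmethod
    def load(cls, path: str | Path) -> "PathGNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]), meta["n_genes"])
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
            for name in model.params:
                model.params[name] = data[name]
        return model
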