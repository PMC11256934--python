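"""Desk-scale internal studies on synthetic data.

Three scripted comparisons probe the properties the path-operator design
is meant to deliver:

* a receptive-field sweep against a plain GCN baseline — deep Laplacian
  message passing over-smooths while the path model degrades little;
* a graph-modality ablation (spatial-only / gene-only / both);
* an operator-sharing ablation over the four tying modes.

All variants inside one comparison share masks, fixtures and walk seeds;
each run record carries a fingerprint of its mask split so that is
checkable after the fact.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .graphs import HeteroGraph, build_hetero_graph
from .io import ExpressionDataset, MaskSplit, apply_mask, make_masks, normalize, select_hvg
from .model import ModelConfig, PathGNN, count_parameters
from .training import TrainConfig, TrainReport, fit_loop, train, warm_start_output
from .evaluation import compute_metrics, extract_masked_vectors

logger = logging.getLogger(__name__)

__all__ = [
    "SweepResult",
    "GCNModel",
    "baseline_gcn",
    "column_mean_impute",
    "receptive_field_sweep",
    "modality_ablation",
    "operator_ablation",
    "prepare_instance",
    "DESK_MODEL",
    "DESK_TRAIN",
]

# desk-scale defaults for the sweeps: small enough that a full study of
# many training runs completes in minutes on one CPU core
DESK_MODEL = ModelConfig(L=2, d_emb=32, k_s=4, k_g=4, T_s=4, T_g=4)
DESK_TRAIN = TrainConfig(max_epochs=150, patience=20, lr=5e-3)


@dataclass
class SweepResult:
    """Per-grid-value metric summary (mean +- sd over seeds)."""

    axis: str
    values: list
    mean: list[float] = field(default_factory=list)
    sd: list[float] = field(default_factory=list)
    n_seeds: int = 0
    records: list[dict] = field(default_factory=list)

    def summarize(self) -> None:
        self.mean, self.sd = [], []
        for v in self.values:
            r = [rec["rmse"] for rec in self.records if rec[self.axis] == v]
            self.mean.append(float(np.mean(r)))
            self.sd.append(float(np.std(r)))
        self.n_seeds = len({rec["seed"] for rec in self.records})

    def to_tsv(self, path) -> None:
        lines = [f"{self.axis}\tmean_rmse\tsd_rmse\tn_seeds"]
        for v, m, s in zip(self.values, self.mean, self.sd):
            lines.append(f"{v}\t{m:.6f}\t{s:.6f}\t{self.n_seeds}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def mask_fingerprint(split: MaskSplit) -> str:
    h = hashlib.sha256()
    for arr in (split.test_idx, split.val_idx, split.train_idx):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def prepare_instance(
    dataset: ExpressionDataset,
    seed: int,
    n_hvg: int = 100,
    knn_k: int = 6,
    d_thr: float | None = None,
) -> tuple[ExpressionDataset, MaskSplit, HeteroGraph]:
    """Normalise, draw masks, and build graphs from the MASKED matrix.

    The gene-similarity graph is constructed from the observed (masked)
    values only, so held-out entries cannot inform the graph.
    """
    norm = normalize(dataset)
    split = make_masks(norm, 0.10, 0.10, seed=seed)
    obs = apply_mask(norm, split)
    hvg = select_hvg(obs, n_hvg)
    hetero = build_hetero_graph(obs, hvg, d_thr=d_thr, knn_k=knn_k)
    return norm, split, hetero


def column_mean_impute(X_target: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Impute every entry with its gene's mean over the training entries.

    Genes with no training entry fall back to the global training mean.
    The usual sanity baseline for masked-entry imputation.
    """
    X_target = np.asarray(X_target, dtype=float)
    n, m = X_target.shape
    vals = X_target[train_idx[:, 0], train_idx[:, 1]]
    sums = np.bincount(train_idx[:, 1], weights=vals, minlength=m)
    counts = np.bincount(train_idx[:, 1], minlength=m)
    global_mean = vals.mean()
    means = np.where(counts > 0, sums / np.maximum(counts, 1), global_mean)
    return np.tile(means, (n, 1))


# ---------------------------------------------------------------------------
# GCN baseline
# ---------------------------------------------------------------------------

class GCNModel:
    """Minimal mean-aggregation GCN over the union of both edge sets.

    ``depth`` rounds of symmetric-normalised neighbour averaging
    (A_hat = D^-1/2 (A + I) D^-1/2), each followed by a learned linear
    map and ReLU, between the same linear encoder and MLP decoder as the
    path model.  Receptive field = depth hops.  Serves as the
    over-smoothing comparison anchor only.
    """

    def __init__(self, hetero: HeteroGraph, n_genes: int, depth: int, d_emb: int = 32, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        self.n_genes = n_genes
        self.d = d_emb
        self.A_hat = self._normalized_adjacency(hetero)
        rng = np.random.default_rng(seed)
        m, d = n_genes, d_emb

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self.params: dict[str, np.ndarray] = {
            "enc_W": glorot(m, d, (m, d)),
            "enc_b": np.zeros(d),
            "dec_W1": glorot(d, d, (d, d)),
            "dec_b1": np.zeros(d),
            "dec_W2": glorot(d, m, (d, m)),
            "dec_b2": np.zeros(m),
        }
        for layer in range(depth):
            self.params[f"W_l{layer}"] = glorot(d, d, (d, d))
            self.params[f"b_l{layer}"] = np.zeros(d)

    @staticmethod
    def _normalized_adjacency(hetero: HeteroGraph) -> sp.csr_matrix:
        n = hetero.n_nodes
        edges = np.concatenate([hetero.spatial.edges, hetero.gene.edges])
        if len(edges):
            edges = np.unique(np.sort(edges, axis=1), axis=0)
            rows = np.concatenate([edges[:, 0], edges[:, 1], np.arange(n)])
            cols = np.concatenate([edges[:, 1], edges[:, 0], np.arange(n)])
        else:
            rows = cols = np.arange(n)
        a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        deg = np.asarray(a.sum(axis=1)).ravel()
        dinv = 1.0 / np.sqrt(deg)
        return sp.csr_matrix(sp.diags(dinv) @ a @ sp.diags(dinv))

    @staticmethod
    def aggregate(A_hat: sp.spmatrix, f: np.ndarray) -> np.ndarray:
        """One round of symmetric-normalised neighbour averaging."""
        return np.asarray(A_hat @ f)

    def forward(self, X_obs: np.ndarray, return_cache: bool = False):
        P = self.params
        f = X_obs @ P["enc_W"] + P["enc_b"]
        cache = {"X_obs": X_obs, "layers": []}
        for layer in range(self.depth):
            af = self.aggregate(self.A_hat, f)
            z = af @ P[f"W_l{layer}"] + P[f"b_l{layer}"]
            cache["layers"].append({"af": af, "z": z})
            f = np.maximum(z, 0.0)
        cache["f_L"] = f
        h = np.maximum(f @ P["dec_W1"] + P["dec_b1"], 0.0)
        cache["dec_h"] = h
        X_hat = h @ P["dec_W2"] + P["dec_b2"]
        if return_cache:
            return X_hat, cache
        return X_hat

    def backward(self, cache: dict, grad_Xhat: np.ndarray) -> dict[str, np.ndarray]:
        P = self.params
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        h = cache["dec_h"]
        grads["dec_W2"] = h.T @ grad_Xhat
        grads["dec_b2"] = grad_Xhat.sum(axis=0)
        gh = grad_Xhat @ P["dec_W2"].T
        gz = gh * (h > 0)
        grads["dec_W1"] = cache["f_L"].T @ gz
        grads["dec_b1"] = gz.sum(axis=0)
        gf = gz @ P["dec_W1"].T
        for layer in reversed(range(self.depth)):
            lc = cache["layers"][layer]
            gz = gf * (lc["z"] > 0)
            grads[f"W_l{layer}"] = lc["af"].T @ gz
            grads[f"b_l{layer}"] = gz.sum(axis=0)
            gf = self.aggregate(self.A_hat, gz @ P[f"W_l{layer}"].T)  # A_hat symmetric
        grads["enc_W"] = cache["X_obs"].T @ gf
        grads["enc_b"] = gf.sum(axis=0)
        return grads


def baseline_gcn(
    hetero: HeteroGraph,
    dataset: ExpressionDataset,
    split: MaskSplit,
    depth: int,
    tcfg: TrainConfig | None = None,
    d_emb: int = 32,
    seed: int = 0,
) -> tuple[np.ndarray, TrainReport]:
    """Train the GCN baseline with the identical masked loss and early
    stopping; returns the imputed matrix and the training report."""
    tcfg = tcfg or replace(DESK_TRAIN, seed=seed)
    X_target = dataset.dense()
    X_obs = apply_mask(dataset, split).dense()
    model = GCNModel(hetero, dataset.n_genes, depth, d_emb=d_emb, seed=seed)
    warm_start_output(model, X_target, split)
    report = fit_loop(
        model, X_obs, X_target, split, tcfg,
        lambda epoch: model.forward(X_obs, return_cache=True),
    )
    X_hat = model.forward(X_obs)
    if len(split.test_idx):
        x_hat, x_gt = extract_masked_vectors(X_hat, X_target, split.test_idx)
        report.test_metrics = compute_metrics(x_hat, x_gt)
    return X_hat, report


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _train_path_model(norm, split, hetero, mcfg: ModelConfig, tcfg: TrainConfig):
    model = PathGNN(mcfg, norm.n_genes)
    _, report = train(model, norm, split, hetero, tcfg)
    return report


def receptive_field_sweep(
    dataset: ExpressionDataset,
    fields: list[int],
    models: tuple[str, ...] = ("path", "gcn"),
    seeds: list[int] = (0, 1, 2, 3, 4),
    base_model: ModelConfig = DESK_MODEL,
    base_train: TrainConfig = DESK_TRAIN,
    L_fixed: int = 2,
) -> dict[str, SweepResult]:
    """Test RMSE as a function of receptive field for both model families.

    For the GCN the receptive field R is its depth.  For the path model
    R = (k - 1) * L with L fixed and the walk length k varied, so a field
    R needs k = R / L + 1 (R must be divisible by L).
    """
    results = {name: SweepResult(axis="field", values=list(fields)) for name in models}
    for seed in seeds:
        norm, split, hetero = prepare_instance(dataset, seed=seed)
        fp = mask_fingerprint(split)
        for R in fields:
            if "path" in models:
                if R % L_fixed:
                    raise ValueError(f"receptive field {R} not divisible by L={L_fixed}")
                k = R // L_fixed + 1
                mcfg = replace(base_model, L=L_fixed, k_s=k, k_g=k, seed=seed)
                tcfg = replace(base_train, seed=seed)
                report = _train_path_model(norm, split, hetero, mcfg, tcfg)
                results["path"].records.append(
                    {"field": R, "seed": seed, "rmse": report.test_metrics.rmse, "mask": fp}
                )
            if "gcn" in models:
                tcfg = replace(base_train, seed=seed)
                _, report = baseline_gcn(
                    hetero, norm, split, depth=R, tcfg=tcfg,
                    d_emb=base_model.d_emb, seed=seed,
                )
                results["gcn"].records.append(
                    {"field": R, "seed": seed, "rmse": report.test_metrics.rmse, "mask": fp}
                )
    for res in results.values():
        res.summarize()
    return results


def modality_ablation(
    dataset: ExpressionDataset,
    seeds: list[int] = (0, 1, 2, 3, 4),
    base_model: ModelConfig = DESK_MODEL,
    base_train: TrainConfig = DESK_TRAIN,
) -> dict[str, SweepResult]:
    """Spatial-only (var_s) vs gene-only (var_g) vs full (var_h) variants.

    All three variants of one seed share the mask split and graphs.
    """
    variants = {"var_s": "spatial", "var_g": "gene", "var_h": "both"}
    results = {name: SweepResult(axis="variant", values=[name]) for name in variants}
    for seed in seeds:
        norm, split, hetero = prepare_instance(dataset, seed=seed)
        fp = mask_fingerprint(split)
        for name, modality in variants.items():
            mcfg = replace(base_model, modality=modality, seed=seed)
            tcfg = replace(base_train, seed=seed)
            report = _train_path_model(norm, split, hetero, mcfg, tcfg)
            results[name].records.append(
                {"variant": name, "seed": seed, "rmse": report.test_metrics.rmse, "mask": fp}
            )
    for res in results.values():
        res.summarize()
    return results


def operator_ablation(
    dataset: ExpressionDataset,
    modes: tuple[str, ...] = ("op_glo", "op_cha", "op_lay", "op_ind"),
    seeds: list[int] = (0, 1, 2, 3, 4),
    base_model: ModelConfig = DESK_MODEL,
    base_train: TrainConfig = DESK_TRAIN,
) -> SweepResult:
    """Compare the four operator-sharing modes under one protocol."""
    result = SweepResult(axis="mode", values=list(modes))
    for seed in seeds:
        norm, split, hetero = prepare_instance(dataset, seed=seed)
        fp = mask_fingerprint(split)
        for mode in modes:
            mcfg = replace(base_model, share_mode=mode, seed=seed)
            tcfg = replace(base_train, seed=seed)
            report = _train_path_model(norm, split, hetero, mcfg, tcfg)
            result.records.append(
                {
                    "mode": mode,
                    "seed": seed,
                    "rmse": report.test_metrics.rmse,
                    "mask": fp,
                    "n_operator_params": count_parameters(mcfg, norm.n_genes)["operators"],
                }
            )
    result.summarize()
    return result
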