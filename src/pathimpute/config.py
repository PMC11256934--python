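"""Configuration resolution and the end-to-end pipeline.

A single nested default tree (mirroring the recommended model settings)
is overlaid first by an optional YAML file and then by ``key.path=value``
command-line overrides.  Unknown keys are rejected with a nearest-key
suggestion; values are coerced to the type of the default they replace.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import compute_metrics, extract_masked_vectors
from .graphs import build_hetero_graph
from .io import (
    ExpressionDataset,
    apply_mask,
    make_masks,
    normalize,
    read_coords,
    read_counts,
    select_hvg,
    write_counts,
)
from .model import ModelConfig, PathGNN
from .simulate import SimConfig, simulate
from .training import TrainConfig, train

logger = logging.getLogger(__name__)

__all__ = ["DEFAULTS", "resolve_config", "run_pipeline", "RunManifest", "StageError"]

DEFAULTS: dict = {
    "seed": 0,
    "data": {
        "normalize": "lognorm",
        "scale_factor": 1e4,
        "transpose": False,
        "min_cells_per_gene": 0,
        "min_genes_per_cell": 0,
    },
    "masks": {"test_frac": 0.10, "val_frac": 0.10},
    "graph": {"d_thr": None, "gene_knn": 6, "n_hvg": 3100},
    "model": {
        "L": 4,
        "d_emb": 64,
        "k_s": 8,
        "k_g": 8,
        "T_s": 8,
        "T_g": 8,
        "q_s": 1.0,
        "q_g": 1.0,
        "p": 1.0,
        "share_mode": "op_ind",
        "raw_features": False,
        "modality": "both",
    },
    "train": {
        "max_epochs": 1000,
        "patience": 50,
        "lr": 1e-3,
        "weight_decay": 1e-5,
    },
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _flatten(tree: dict, prefix: str = "") -> list[str]:
    keys = []
    for k, v in tree.items():
        path = f"{prefix}{k}"
        keys.append(path)
        if isinstance(v, dict):
            keys.extend(_flatten(v, path + "."))
    return keys


def _coerce(value, default, key: str):
    if default is None or value is None:
        return value
    if isinstance(default, bool):
        if isinstance(value, bool):
            return value
        if str(value).lower() in ("true", "1", "yes"):
            return True
        if str(value).lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"key {key!r}: cannot interpret {value!r} as a boolean")
    if isinstance(default, int) and not isinstance(default, bool):
        try:
            f = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"key {key!r}: expected an integer, got {value!r}") from exc
        if f != int(f):
            raise ConfigError(f"key {key!r}: expected an integer, got {value!r}")
        return int(f)
    if isinstance(default, float):
        try:
            return float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"key {key!r}: expected a number, got {value!r}") from exc
    return type(default)(value)


def _merge(base: dict, overlay: dict, prefix: str = "") -> None:
    valid = _flatten(DEFAULTS)
    for k, v in overlay.items():
        path = f"{prefix}{k}"
        if k not in base:
            hint = difflib.get_close_matches(path, valid, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown configuration key {path!r}{suggestion}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ConfigError(f"key {path!r} expects a section, got {v!r}")
            _merge(base[k], v, path + ".")
        else:
            base[k] = _coerce(v, base[k], path)


def resolve_config(file: str | Path | None = None, overrides: list[str] | None = None) -> dict:
    """defaults <- file <- overrides, validated against the default tree."""
    cfg = copy.deepcopy(DEFAULTS)
    if file is not None:
        loaded = yaml.safe_load(Path(file).read_text())
        if loaded:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {file} must contain a mapping")
            _merge(cfg, loaded)
    for item in overrides or []:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key.path=value")
        key, _, raw = item.partition("=")
        node: dict = {}
        leaf = node
        parts = key.split(".")
        for part in parts[:-1]:
            leaf[part] = {}
            leaf = leaf[part]
        leaf[parts[-1]] = yaml.safe_load(raw)
        _merge(cfg, node)
    return cfg


def model_config_from(cfg: dict, seed: int | None = None) -> ModelConfig:
    return ModelConfig(seed=cfg["seed"] if seed is None else seed, **cfg["model"])


def train_config_from(cfg: dict, seed: int | None = None) -> TrainConfig:
    return TrainConfig(seed=cfg["seed"] if seed is None else seed, **cfg["train"])


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    out_dir: str | Path,
    config: dict | None = None,
    counts: str | Path | None = None,
    coords: str | Path | None = None,
    sim: SimConfig | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Load-or-simulate -> normalise -> mask -> graphs -> train -> evaluate.

    Every intermediate artifact is persisted under ``out_dir`` (masks,
    checkpoint, training report, metrics, resolved config, manifest), so
    the run is re-derivable from the directory alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = copy.deepcopy(config) if config else copy.deepcopy(DEFAULTS)
    if seed is not None:
        cfg["seed"] = int(seed)
    manifest = RunManifest(
        config=cfg,
        seed=cfg["seed"],
        versions={"pathimpute": __version__, "numpy": np.__version__},
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            manifest.to_json(out / "manifest.json")
            raise StageError(name, exc) from exc

    if counts is not None:
        data = stage("read_counts", read_counts, counts, transpose=cfg["data"]["transpose"])
        manifest.input_checksums[str(counts)] = _checksum(Path(counts))
        if coords is not None:
            data.coords = stage("read_coords", read_coords, coords, data.cell_ids)
            manifest.input_checksums[str(coords)] = _checksum(Path(coords))
        if data.coords is None:
            raise StageError("read_coords", ValueError("no spatial coordinates provided"))
    else:
        sim = sim or SimConfig(seed=cfg["seed"])
        data, _ = stage("simulate", simulate, sim)

    norm = stage(
        "normalize", normalize, data,
        scheme=cfg["data"]["normalize"], scale_factor=cfg["data"]["scale_factor"],
    )
    split = stage(
        "make_masks", make_masks, norm,
        cfg["masks"]["test_frac"], cfg["masks"]["val_frac"], cfg["seed"],
    )
    split.to_json(out / "masks.json")
    obs = apply_mask(norm, split)
    hvg = stage("select_hvg", select_hvg, obs, cfg["graph"]["n_hvg"])
    hetero = stage(
        "build_graphs", build_hetero_graph, obs, hvg,
        d_thr=cfg["graph"]["d_thr"], knn_k=cfg["graph"]["gene_knn"],
    )
    model = PathGNN(model_config_from(cfg), norm.n_genes)
    model, report = stage(
        "train", train, model, norm, split, hetero, train_config_from(cfg)
    )
    model.save(out / "checkpoint.npz")
    (out / "train_report.json").write_text(
        json.dumps(
            {
                "train_loss": report.train_loss,
                "val_rmse": report.val_rmse,
                "best_epoch": report.best_epoch,
                "stopped_epoch": report.stopped_epoch,
            }
        )
    )
    if report.test_metrics is not None:
        report.test_metrics.to_json(out / "metrics.json")
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    manifest.outputs = {
        name: str(out / name)
        for name in ("masks.json", "checkpoint.npz", "train_report.json", "metrics.json", "config.yaml")
        if (out / name).exists()
    }
    manifest.to_json(out / "manifest.json")
    return manifest
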