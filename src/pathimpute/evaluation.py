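"""Benchmark metrics on the held-out test entries.

The test mask selects entries of the ground-truth matrix; the imputed and
true values at those entries are flattened to two vectors (row-major
order) and compared with mean L1 distance, cosine similarity and RMSE.
L1 distance is reported as the MEAN absolute difference (per-entry scale);
a summed variant is available via ``l1_reduction='sum'``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["MetricReport", "extract_masked_vectors", "compute_metrics"]


@dataclass
class MetricReport:
    l1_distance: float
    cosine_similarity: float
    rmse: float
    n_entries: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.cosine_similarity <= 1.0 + 1e-12:
            raise ValueError("cosine similarity outside [-1, 1]")
        if self.rmse < 0 or self.l1_distance < 0:
            raise ValueError("distances must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))


def extract_masked_vectors(
    X_hat: np.ndarray, X_gt: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pull the masked entries out of both matrices in row-major index order."""
    idx = np.asarray(idx, dtype=int).reshape(-1, 2)
    if len(idx) == 0:
        raise ValueError("empty index set")
    n, m = np.asarray(X_hat).shape
    if idx[:, 0].min() < 0 or idx[:, 0].max() >= n or idx[:, 1].min() < 0 or idx[:, 1].max() >= m:
        raise IndexError("mask index out of bounds")
    order = np.lexsort((idx[:, 1], idx[:, 0]))
    idx = idx[order]
    return (
        np.asarray(X_hat, dtype=float)[idx[:, 0], idx[:, 1]],
        np.asarray(X_gt, dtype=float)[idx[:, 0], idx[:, 1]],
    )


def compute_metrics(
    x_hat: np.ndarray, x_gt: np.ndarray, l1_reduction: str = "mean"
) -> MetricReport:
    """Mean L1 distance, cosine similarity and RMSE between two vectors."""
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    x_gt = np.asarray(x_gt, dtype=float).ravel()
    if x_hat.shape != x_gt.shape or len(x_hat) == 0:
        raise ValueError("vectors must be nonempty and of equal length")
    diff = x_hat - x_gt
    if l1_reduction == "mean":
        l1 = float(np.abs(diff).mean())
    elif l1_reduction == "sum":
        l1 = float(np.abs(diff).sum())
    else:
        raise ValueError("l1_reduction must be 'mean' or 'sum'")
    norm_hat, norm_gt = np.linalg.norm(x_hat), np.linalg.norm(x_gt)
    if norm_hat == 0 or norm_gt == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    cosine = float(np.clip(x_hat @ x_gt / (norm_hat * norm_gt), -1.0, 1.0))
    rmse = float(np.sqrt(np.mean(diff**2)))
    return MetricReport(
        l1_distance=l1,
        cosine_similarity=cosine,
        rmse=rmse,
        n_entries=len(x_hat),
    )
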