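"""Reading, writing, normalising and masking spatial expression matrices.

The package works on a cell-by-gene nonnegative matrix together with a
per-cell table of 2-D spatial coordinates.  Everything downstream (graph
construction, walk sampling, the model) consumes the containers defined
here.  Orientation is fixed as cells x genes everywhere; transposed input
is handled only via the explicit ``transpose`` flag, never guessed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "MaskSplit",
    "HVGSelection",
    "read_counts",
    "write_counts",
    "read_coords",
    "normalize",
    "select_hvg",
    "make_masks",
    "apply_mask",
]


class FormatError(ValueError):
    """Malformed input file."""


class AlignmentError(ValueError):
    """Cell identifiers of two inputs cannot be reconciled."""


@dataclass
class ExpressionDataset:
    """A cell-by-gene expression matrix with spatial coordinates.

    Attributes
    ----------
    values
        Nonnegative matrix of shape (n_cells, n_genes); dense ndarray or
        scipy sparse.  Sparse input stays sparse through normalisation
        and masking.
    cell_ids, gene_ids
        Unique string identifiers, one per row / column.
    coords
        (n_cells, 2) spatial coordinates in platform units.
    layer_labels
        Optional per-cell categorical annotation (synthetic data only).
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    coords: np.ndarray | None = None
    layer_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != m:
            raise ValueError(
                f"id lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids are not unique")
        if self.min() < 0:
            raise ValueError("expression matrix contains negative entries")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValueError(
                    f"coords shape {self.coords.shape} does not match n_cells={n}"
                )

    # -- small conveniences -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        if sp.issparse(self.values):
            return self.values.data.min() if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def nonzero_indices(self) -> np.ndarray:
        """(Z, 2) array of (cell, gene) indices of nonzero entries, row-major."""
        if sp.issparse(self.values):
            coo = sp.coo_matrix(self.values)
            idx = np.column_stack([coo.row, coo.col])
        else:
            idx = np.argwhere(self.values != 0)
        order = np.lexsort((idx[:, 1], idx[:, 0]))
        return idx[order]

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            coords=None if self.coords is None else self.coords.copy(),
            layer_labels=None
            if self.layer_labels is None
            else self.layer_labels.copy(),
        )


@dataclass
class MaskSplit:
    """Disjoint train/validation/test partition of the nonzero entries.

    Each index set is an integer array of shape (n_entries, 2) holding
    (cell, gene) pairs.  The union of the three sets is exactly the
    nonzero set of the ground-truth matrix they were drawn from.
    """

    test_idx: np.ndarray
    val_idx: np.ndarray
    train_idx: np.ndarray
    seed: int
    fractions: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("test_idx", "val_idx", "train_idx"):
            arr = np.asarray(getattr(self, name), dtype=int).reshape(-1, 2)
            setattr(self, name, arr)

    @property
    def n_nonzero(self) -> int:
        return len(self.test_idx) + len(self.val_idx) + len(self.train_idx)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": int(self.seed),
            "fractions": list(self.fractions),
            "test_idx": self.test_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "train_idx": self.train_idx.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaskSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            test_idx=np.asarray(payload["test_idx"], dtype=int).reshape(-1, 2),
            val_idx=np.asarray(payload["val_idx"], dtype=int).reshape(-1, 2),
            train_idx=np.asarray(payload["train_idx"], dtype=int).reshape(-1, 2),
            seed=int(payload["seed"]),
            fractions=tuple(payload["fractions"]),
        )


@dataclass
class HVGSelection:
    """Indices of the selected highly variable genes, most variable first."""

    gene_indices: np.ndarray
    n_hvg: int

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=int)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_sidecar_ids(path: Path, names: Sequence[str], n: int, prefix: str) -> list[str]:
    for name in names:
        candidate = path.parent / name
        if candidate.exists():
            ids = [line.split("\t")[0] for line in candidate.read_text().splitlines() if line]
            if len(ids) != n:
                raise FormatError(
                    f"{candidate.name} has {len(ids)} entries but matrix axis is {n}"
                )
            return ids
    return [f"{prefix}{i}" for i in range(n)]


def read_counts(
    path: str | Path,
    format: str | None = None,
    transpose: bool = False,
) -> ExpressionDataset:
    """Read a cell-by-gene count matrix.

    Supported formats: ``mtx`` (Matrix Market triplet, rows = cells, with
    optional ``barcodes.tsv`` / ``features.tsv`` or ``genes.tsv`` sidecars),
    ``h5ad`` (cells as observations; ``obsm['spatial']`` picked up as
    coordinates when present) and ``csv`` (first column = cell id, header
    row = gene ids).  ``transpose=True`` flips a genes-by-cells file (the
    raw 10x convention) into cell-by-gene orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mtx": "mtx", ".h5ad": "h5ad", ".csv": "csv", ".tsv": "csv"}.get(
            path.suffix.lower(), ""
        )
    if format == "mtx":
        try:
            mat = mmread(str(path))
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        if transpose:
            mat = sp.csr_matrix(mat.T)
        n, m = mat.shape
        cell_ids = _read_sidecar_ids(path, ["barcodes.tsv"], n, "cell_")
        gene_ids = _read_sidecar_ids(path, ["features.tsv", "genes.tsv"], m, "gene_")
        return ExpressionDataset(values=mat, cell_ids=cell_ids, gene_ids=gene_ids)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(str(path))
        values = adata.X
        if transpose:
            values = values.T
        values = sp.csr_matrix(values) if sp.issparse(values) else np.asarray(values)
        coords = None
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
        return ExpressionDataset(
            values=values,
            cell_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            coords=coords,
        )
    if format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        values = df.to_numpy(dtype=float)
        if transpose:
            values = values.T
            cell_ids, gene_ids = list(map(str, df.columns)), list(map(str, df.index))
        else:
            cell_ids, gene_ids = list(map(str, df.index)), list(map(str, df.columns))
        return ExpressionDataset(values=values, cell_ids=cell_ids, gene_ids=gene_ids)
    raise FormatError(f"unsupported format {format!r} for {path}")


def write_counts(data: ExpressionDataset, path: str | Path, format: str = "mtx") -> None:
    """Write the matrix back out; inverse of :func:`read_counts` on the nonzero set."""
    path = Path(path)
    if format == "mtx":
        mat = data.values if sp.issparse(data.values) else sp.coo_matrix(data.values)
        mmwrite(str(path), sp.coo_matrix(mat))
        (path.parent / "barcodes.tsv").write_text("\n".join(data.cell_ids) + "\n")
        (path.parent / "features.tsv").write_text("\n".join(data.gene_ids) + "\n")
    elif format == "csv":
        pd.DataFrame(data.dense(), index=data.cell_ids, columns=data.gene_ids).to_csv(path)
    elif format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=sp.csr_matrix(data.values) if sp.issparse(data.values) else data.values,
            obs=pd.DataFrame(index=data.cell_ids),
            var=pd.DataFrame(index=data.gene_ids),
        )
        if data.coords is not None:
            adata.obsm["spatial"] = data.coords
        adata.write_h5ad(str(path))
    else:
        raise FormatError(f"unsupported format {format!r}")


def read_coords(path: str | Path, cell_ids: Sequence[str] | None = None) -> np.ndarray:
    """Read an (n, 2) spatial coordinate table (CSV/TSV with header).

    If the table carries a cell-id column (any non-numeric first column)
    and ``cell_ids`` is given, rows are realigned to that order; a missing
    or surplus id raises :class:`AlignmentError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise FormatError(f"coordinate table {path} needs at least two columns")
    first_numeric = pd.api.types.is_numeric_dtype(df.iloc[:, 0])
    if not first_numeric:
        ids = df.iloc[:, 0].astype(str)
        coord_cols = df.iloc[:, 1:3]
    else:
        ids = None
        coord_cols = df.iloc[:, 0:2]
    try:
        coords = coord_cols.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric coordinate in {path}: {exc}") from exc
    if coords.shape[1] != 2:
        raise FormatError("expected exactly two coordinate columns")
    if cell_ids is not None:
        if ids is None:
            if len(coords) != len(cell_ids):
                raise AlignmentError(
                    f"coords have {len(coords)} rows but counts have {len(cell_ids)} cells "
                    "and no id column to realign by"
                )
            return coords
        lookup = {c: i for i, c in enumerate(ids)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise AlignmentError(
                f"coordinate table {path} is missing cells: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return coords[[lookup[c] for c in cell_ids]]
    return coords


# ---------------------------------------------------------------------------
# Normalisation and gene selection
# ---------------------------------------------------------------------------

def normalize(
    data: ExpressionDataset,
    scheme: str = "lognorm",
    scale_factor: float = 1e4,
) -> ExpressionDataset:
    """Library-size normalise and log-transform the counts.

    ``lognorm`` scales each cell's counts to ``scale_factor`` total and
    applies log1p; exact zeros stay exactly zero, so the nonzero set (and
    therefore any mask drawn from it) is unchanged.  ``none`` returns a
    copy untouched.  All-zero cells are left all-zero with a warning.
    """
    if scheme == "none":
        return data.copy()
    if scheme != "lognorm":
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    out = data.copy()
    if sp.issparse(out.values):
        mat = sp.csr_matrix(out.values, dtype=float)
        totals = np.asarray(mat.sum(axis=1)).ravel()
        zero_cells = totals == 0
        if zero_cells.any():
            logger.warning("%d all-zero cells left unnormalized", int(zero_cells.sum()))
        safe = np.where(zero_cells, 1.0, totals)
        scale = scale_factor / safe
        mat = sp.csr_matrix(sp.diags(scale) @ mat)
        mat.data = np.log1p(mat.data)
        out.values = mat
    else:
        mat = np.asarray(out.values, dtype=float).copy()
        totals = mat.sum(axis=1)
        zero_cells = totals == 0
        if zero_cells.any():
            logger.warning("%d all-zero cells left unnormalized", int(zero_cells.sum()))
        safe = np.where(zero_cells, 1.0, totals)
        mat = np.log1p(mat * (scale_factor / safe)[:, None])
        out.values = mat
    return out


def dispersion_scores(values: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Per-gene dispersion (variance / mean) across cells; 0 for silent genes."""
    if sp.issparse(values):
        mat = sp.csr_matrix(values, dtype=float)
        mean = np.asarray(mat.mean(axis=0)).ravel()
        sq = np.asarray(mat.multiply(mat).mean(axis=0)).ravel()
        var = sq - mean**2
    else:
        mat = np.asarray(values, dtype=float)
        mean = mat.mean(axis=0)
        var = mat.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return disp


def select_hvg(data: ExpressionDataset, n_hvg: int = 3100) -> HVGSelection:
    """Rank genes by dispersion (variance over mean) and keep the top ``n_hvg``.

    Deterministic: ties are broken by ascending gene index.  Requesting
    more genes than exist returns all of them with a warning.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    m = data.n_genes
    if n_hvg > m:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {m} available genes; keeping all",
            stacklevel=2,
        )
        n_hvg = m
    disp = dispersion_scores(data.values)
    order = np.lexsort((np.arange(m), -disp))
    return HVGSelection(gene_indices=order[:n_hvg], n_hvg=n_hvg)


# ---------------------------------------------------------------------------
# Masking protocol
# ---------------------------------------------------------------------------

def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def make_masks(
    data: ExpressionDataset,
    test_frac: float = 0.10,
    val_frac: float = 0.10,
    seed: int = 0,
) -> MaskSplit:
    """Partition the nonzero entries into train / validation / test sets.

    Test and validation entries are drawn uniformly at random without
    replacement over the Z nonzero entries, with |test| = round(test_frac*Z)
    and |val| = round(val_frac*Z) (half-values round down); everything else
    is training.  Reproducible for a fixed seed.
    """
    if test_frac + val_frac >= 1:
        raise ValueError("test_frac + val_frac must be < 1")
    nz = data.nonzero_indices()
    z = len(nz)
    if z == 0:
        raise ValueError("matrix has no nonzero entries to mask")
    n_test = _round_half_down(test_frac * z)
    n_val = _round_half_down(val_frac * z)
    if n_test + n_val > z:
        raise ValueError(
            f"requested {n_test} test + {n_val} validation entries "
            f"but only {z} nonzeros exist"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(z)
    return MaskSplit(
        test_idx=nz[perm[:n_test]],
        val_idx=nz[perm[n_test : n_test + n_val]],
        train_idx=nz[perm[n_test + n_val :]],
        seed=seed,
        fractions=(test_frac, val_frac),
    )


def apply_mask(data: ExpressionDataset, split: MaskSplit) -> ExpressionDataset:
    """Zero out the test and validation entries; the input is not modified."""
    out = data.copy()
    idx = np.concatenate([split.test_idx, split.val_idx]) if (
        len(split.test_idx) or len(split.val_idx)
    ) else np.empty((0, 2), dtype=int)
    if len(idx):
        if idx[:, 0].max() >= data.n_cells or idx[:, 1].max() >= data.n_genes:
            raise IndexError("mask index out of bounds for the matrix")
        if sp.issparse(out.values):
            mat = sp.lil_matrix(out.values)
            mat[idx[:, 0], idx[:, 1]] = 0
            out.values = sp.csr_matrix(mat)
            out.values.eliminate_zeros()
        else:
            out.values = np.asarray(out.values, dtype=float).copy()
            out.values[idx[:, 0], idx[:, 1]] = 0
    return out
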