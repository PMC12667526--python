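"""Reading and preprocessing paired CITE-seq RNA/ADT count matrices.

The pipeline mirrors standard single-cell practice: drop all-zero
features, keep the top-``d`` most variable genes, depth-normalize each
cell, then log1p-transform and standardize every feature. RNA goes
through all four stages; the (already low-dimensional) ADT panel skips
gene selection and keeps every nonzero feature.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

__all__ = [
    "RawOmicsPair",
    "ProcessedOmicsPair",
    "read_paired_counts",
    "filter_zero_genes",
    "select_hvg",
    "normalize_cells",
    "log_scale",
    "preprocess",
]


@dataclass
class RawOmicsPair:
    """Paired raw counts over an identical, identically ordered cell set.

    ``rna_counts`` is cells x genes, ``adt_counts`` cells x proteins.
    ``labels``/``batches`` are optional per-cell integer annotations.
    """

    rna_counts: np.ndarray
    adt_counts: np.ndarray
    cell_ids: list
    gene_ids: list
    adt_ids: list
    labels: np.ndarray | None = None
    batches: np.ndarray | None = None

    def __post_init__(self):
        self.rna_counts = _dense(self.rna_counts)
        self.adt_counts = _dense(self.adt_counts)
        if self.rna_counts.shape[0] != self.adt_counts.shape[0]:
            raise ValueError(
                f"cell counts differ: RNA {self.rna_counts.shape[0]} vs "
                f"ADT {self.adt_counts.shape[0]}"
            )
        if (self.rna_counts < 0).any() or (self.adt_counts < 0).any():
            raise ValueError("count matrices must be non-negative")
        n = self.rna_counts.shape[0]
        for name, ids, dim in [
            ("cell_ids", self.cell_ids, n),
            ("gene_ids", self.gene_ids, self.rna_counts.shape[1]),
            ("adt_ids", self.adt_ids, self.adt_counts.shape[1]),
        ]:
            if len(ids) != dim:
                raise ValueError(f"{name} length {len(ids)} != {dim}")
        for name in ("labels", "batches"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=int)
                if v.shape[0] != n:
                    raise ValueError(f"{name} length {v.shape[0]} != {n} cells")
                setattr(self, name, v)

    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[0]


@dataclass
class ProcessedOmicsPair:
    """Model-ready matrices: HVG-selected, normalized, log1p-scaled."""

    Xr: np.ndarray
    Xa: np.ndarray
    hvg_indices: np.ndarray
    cell_ids: list
    provenance: dict = field(default_factory=dict)
    labels: np.ndarray | None = None
    batches: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.Xr.shape[0]


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=np.float64)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_mtx_triplet(path: str):
    """Read a Matrix Market triplet (matrix + barcodes + features).

    ``path`` may be a directory holding matrix.mtx/barcodes.tsv/features.tsv
    or a ``<prefix>_matrix.mtx`` file with sibling ``<prefix>_barcodes.tsv``
    and ``<prefix>_features.tsv``. The matrix is stored features x cells
    (10x convention) and transposed on read.
    """
    if os.path.isdir(path):
        mtx = os.path.join(path, "matrix.mtx")
        barcodes = os.path.join(path, "barcodes.tsv")
        features = os.path.join(path, "features.tsv")
    else:
        if not path.endswith("_matrix.mtx"):
            raise ValueError(f"expected a directory or *_matrix.mtx file, got {path}")
        prefix = path[: -len("_matrix.mtx")]
        mtx = path
        barcodes = prefix + "_barcodes.tsv"
        features = prefix + "_features.tsv"
    for f in (mtx, barcodes, features):
        if not os.path.exists(f):
            raise FileNotFoundError(f"missing companion file: {f}")
    X = _dense(mmread(mtx)).T  # -> cells x features
    cells = pd.read_csv(barcodes, header=None, sep="\t")[0].astype(str).tolist()
    feats = pd.read_csv(features, header=None, sep="\t")[0].astype(str).tolist()
    return X, cells, feats


def _read_csv(path: str):
    """CSV with a header of feature names and a first column of barcodes."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), df.index.astype(str).tolist(), list(df.columns)


def _read_column(path: str) -> np.ndarray:
    values = pd.read_csv(path, header=None)[0]
    codes, _ = pd.factorize(values)
    if pd.api.types.is_integer_dtype(values):
        return values.to_numpy(dtype=int)
    return codes.astype(int)


def read_paired_counts(
    rna_path: str,
    adt_path: str,
    format: str = "csv",
    labels_path: str | None = None,
    batches_path: str | None = None,
) -> RawOmicsPair:
    """Load both modalities and align them to a common cell ordering.

    Cells are intersected by barcode; the RNA file's ordering (restricted
    to the intersection) defines the output order. Per-cell label/batch
    files are assumed aligned to the RNA barcodes.
    """
    reader = {"mtx": _read_mtx_triplet, "csv": _read_csv}.get(format)
    if reader is None:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")
    Xr, rna_cells, genes = reader(rna_path)
    Xa, adt_cells, adts = reader(adt_path)

    shared = [c for c in rna_cells if c in set(adt_cells)]
    if not shared:
        raise ValueError("no shared cells between RNA and ADT barcodes")
    rna_pos = {c: i for i, c in enumerate(rna_cells)}
    adt_pos = {c: i for i, c in enumerate(adt_cells)}
    rna_idx = np.array([rna_pos[c] for c in shared])
    adt_idx = np.array([adt_pos[c] for c in shared])

    labels = batches = None
    if labels_path is not None:
        labels = _read_column(labels_path)[rna_idx]
    if batches_path is not None:
        batches = _read_column(batches_path)[rna_idx]

    return RawOmicsPair(
        rna_counts=Xr[rna_idx],
        adt_counts=Xa[adt_idx],
        cell_ids=shared,
        gene_ids=genes,
        adt_ids=adts,
        labels=labels,
        batches=batches,
    )


# ---------------------------------------------------------------------------
# preprocessing stages
# ---------------------------------------------------------------------------

def filter_zero_genes(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop features whose total count is zero; return survivors + indices."""
    X = np.asarray(X)
    keep = np.flatnonzero(X.sum(axis=0) > 0)
    if keep.size == 0:
        raise ValueError("no informative features: every column sums to zero")
    return X[:, keep], keep


def select_hvg(X: np.ndarray, d: int, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``d`` most variable features by normalized dispersion.

    Dispersion (variance/mean) is computed on depth-normalized counts,
    then z-scored within ``n_bins`` quantile bins of the mean so that
    highly expressed genes do not dominate the ranking. Ties and
    single-gene bins fall back to the raw dispersion ordering.
    """
    X = np.asarray(X, dtype=np.float64)
    if d >= X.shape[1]:
        return X.copy(), np.arange(X.shape[1])

    depth = X.sum(axis=1, keepdims=True)
    scale = np.where(depth > 0, depth, 1.0)
    Xn = X / scale * np.median(depth[depth > 0]) if (depth > 0).any() else X
    mean = Xn.mean(axis=0)
    var = Xn.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)

    # standardize dispersion within mean-quantile bins
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, X.shape[1]))
    norm_disp = np.zeros_like(dispersion)
    for members in bins:
        if members.size == 0:
            continue
        d_bin = dispersion[members]
        sd = d_bin.std(ddof=1) if members.size > 1 else 0.0
        if sd > 0:
            norm_disp[members] = (d_bin - d_bin.mean()) / sd
        else:
            norm_disp[members] = 0.0

    # a zero-dispersion (constant) feature can never outrank a variable one
    norm_disp[dispersion == 0] = -np.inf
    ranked = np.lexsort((-dispersion, -norm_disp))
    keep = np.sort(ranked[:d])
    return X[:, keep], keep


def normalize_cells(
    X: np.ndarray, target_sum: float = 1e4, cell_ids: list | None = None
) -> np.ndarray:
    """Scale every cell so its total count equals ``target_sum``."""
    X = np.asarray(X, dtype=np.float64)
    totals = X.sum(axis=1)
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        names = [cell_ids[i] for i in bad] if cell_ids is not None else bad.tolist()
        raise ValueError(f"cells with zero total count: {names}")
    return X * (target_sum / totals)[:, None]


def log_scale(X: np.ndarray) -> np.ndarray:
    """log1p transform, then standardize each feature to mean 0, variance 1.

    Constant features map to all-zeros rather than NaN.
    """
    X = np.log1p(np.asarray(X, dtype=np.float64))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    out = (X - mean) / sd
    out[:, X.std(axis=0) == 0] = 0.0
    return out


def preprocess(
    raw: RawOmicsPair, d: int = 500, target_sum: float = 1e4
) -> ProcessedOmicsPair:
    """filter -> HVG (RNA only) -> depth-normalize -> log1p + scale."""
    Xr, rna_kept = filter_zero_genes(raw.rna_counts)
    Xr, hvg_local = select_hvg(Xr, d)
    hvg_indices = rna_kept[hvg_local]
    Xr = normalize_cells(Xr, target_sum, raw.cell_ids)
    Xr = log_scale(Xr)

    Xa, adt_kept = filter_zero_genes(raw.adt_counts)
    Xa = normalize_cells(Xa, target_sum, raw.cell_ids)
    Xa = log_scale(Xa)

    return ProcessedOmicsPair(
        Xr=Xr,
        Xa=Xa,
        hvg_indices=hvg_indices,
        cell_ids=list(raw.cell_ids),
        provenance={
            "hvg_criterion": "binned normalized dispersion",
            "hvg_budget": d,
            "target_sum": target_sum,
            "adt_kept": adt_kept.tolist(),
            "steps": ["filter_zero_genes", "select_hvg", "normalize_cells", "log_scale"],
        },
        labels=None if raw.labels is None else raw.labels.copy(),
        batches=None if raw.batches is None else raw.batches.copy(),
    )
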