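"""Expression loading, filtering, normalization, and adjacent-information profiles.

The pipeline's supervision signal is the *relative isotype expression* of each
cell: the log2(TPM+1) expression of each immunoglobulin heavy-chain constant
region transcript (Ighm, Ighg1, Ighg2b, Ighg2c, Ighg3, Igha, Ighd, Ighe)
divided by the cumulative log2(TPM+1) expression of all eight. These per-cell
simplex vectors — "adjacent profiles" — monotonically track class switch
recombination and are used to shape the autoencoder latent space and to
condition the GAN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.io import mmread, mmwrite

logger = logging.getLogger("pseudocell_tracer")

#: default condition-gene identifiers (mouse IgH constant-region transcripts)
DEFAULT_CHANNELS = ("Ighm", "Ighg1", "Ighg2b", "Ighg2c", "Ighg3", "Igha", "Ighd", "Ighe")

RAW_COUNTS = "raw_counts"
TPM = "tpm"
LOG2_TPM1 = "log2_tpm1"


class FormatError(ValueError):
    """Raised when an on-disk dataset is malformed or incomplete."""


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression matrix with identifier bookkeeping.

    ``normalization_tag`` tracks which scale ``values`` is on:
    ``raw_counts`` -> ``tpm`` -> ``log2_tpm1``. Operations check the tag so
    data cannot be, e.g., log-normalized twice.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalization_tag: str = RAW_COUNTS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes array")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dups = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
                raise ValueError(f"duplicate {name} ids: {dups[:10]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_ids, case_insensitive: bool = False) -> np.ndarray:
        """Column indices of ``gene_ids``, erroring on any that are missing."""
        if case_insensitive:
            lookup = {g.lower(): i for i, g in enumerate(self.gene_ids)}
            keys = [g.lower() for g in gene_ids]
        else:
            lookup = {g: i for i, g in enumerate(self.gene_ids)}
            keys = list(gene_ids)
        missing = [g for g, k in zip(gene_ids, keys) if k not in lookup]
        if missing:
            raise KeyError(f"genes not found: {missing}")
        return np.array([lookup[k] for k in keys], dtype=int)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


@dataclass
class AdjacentProfiles:
    """Per-cell simplex vectors of relative condition-gene expression."""

    weights: np.ndarray  # cells x K, rows sum to 1
    channel_ids: list[str]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(self.channel_ids):
            raise ValueError("weights must be cells x n_channels")
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise ValueError("profile weights must lie in [0, 1]")
        row_sums = self.weights.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            bad = np.flatnonzero(np.abs(row_sums - 1.0) > 1e-9)
            raise ValueError(f"profiles off the simplex at rows {bad[:10].tolist()}")

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    def dominant_channel(self) -> np.ndarray:
        """Index of the highest-weight channel per cell (ties -> lowest index)."""
        return np.argmax(self.weights, axis=1)

    def to_frame(self) -> pd.DataFrame:
        idx = self.cell_ids if self.cell_ids else range(self.n_cells)
        return pd.DataFrame(self.weights, index=pd.Index(idx, name="cell_id"),
                            columns=self.channel_ids)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_expression(path, fmt: str | None = None, *, orientation: str = "cells_by_genes",
                    normalization_tag: str = RAW_COUNTS) -> ExpressionMatrix:
    """Load an expression matrix from MTX (10x convention), CSV/TSV, or HDF5.

    Parameters
    ----------
    path:
        For ``mtx``: the ``matrix.mtx`` file, with ``features.tsv`` (or
        ``genes.tsv``) and ``barcodes.tsv`` beside it. For ``csv``/``tsv``:
        a dense table whose header row holds gene ids and whose first column
        holds cell ids. For ``h5``: an HDF5 file with datasets ``matrix``,
        ``gene_ids``, ``cell_ids``.
    fmt:
        ``mtx``/``csv``/``tsv``/``h5``; inferred from the suffix when omitted.
    orientation:
        ``cells_by_genes`` (default) or ``genes_by_cells`` for transposed
        dense input. MTX input follows the 10x convention (genes x cells)
        and is always transposed internally.
    normalization_tag:
        Declared scale of the values on disk (``raw_counts`` or ``tpm``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"mtx": "mtx", "csv": "csv", "tsv": "tsv", "txt": "tsv",
               "h5": "h5", "hdf5": "h5"}.get(suffix)
        if fmt is None:
            raise FormatError(f"cannot infer format from suffix of {path.name}")
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if fmt == "mtx":
        m = mmread(path)
        mat = np.asarray(m.todense()) if sparse.issparse(m) else np.asarray(m)
        features = _find_companion(path, ("features.tsv", "genes.tsv"))
        barcodes = _find_companion(path, ("barcodes.tsv",))
        gene_ids = _read_id_column(features)
        cell_ids = _read_id_column(barcodes)
        if mat.shape == (len(gene_ids), len(cell_ids)):
            mat = mat.T  # 10x stores genes x cells
        elif mat.shape != (len(cell_ids), len(gene_ids)):
            raise FormatError(
                f"matrix shape {mat.shape} matches neither orientation for "
                f"{len(gene_ids)} features x {len(cell_ids)} barcodes"
            )
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:  # pandas mangles duplicate header names
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dup = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate gene ids in input: {dup[:10]}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(c) for c in df.columns]
        cell_ids = [str(i) for i in df.index]
    elif fmt == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            mat = f["matrix"][...]
            gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][...]]
            cell_ids = [c.decode() if isinstance(c, bytes) else str(c) for c in f["cell_ids"][...]]
        if orientation == "genes_by_cells":
            mat = mat.T
    else:
        raise FormatError(f"unknown format {fmt!r}")

    dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate gene ids in input: {dup[:10]}")
    return ExpressionMatrix(mat, gene_ids, cell_ids, normalization_tag)


def _find_companion(mtx_path: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        for cand in (mtx_path.parent / name, mtx_path.parent / (name + ".gz")):
            if cand.exists():
                return cand
    raise FormatError(
        f"MTX companion file missing: expected one of {names} next to {mtx_path.name}"
    )


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    # 10x features.tsv: ensembl_id, symbol, feature_type -> use the symbol
    col = 1 if df.shape[1] >= 2 else 0
    return [str(v) for v in df.iloc[:, col]]


def save_expression_mtx(expr: ExpressionMatrix, out_dir) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv (10x layout, genes x cells)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / "matrix.mtx"), sparse.csc_matrix(expr.values.T))
    pd.DataFrame({0: expr.gene_ids, 1: expr.gene_ids, 2: "Gene Expression"}).to_csv(
        out_dir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(expr.cell_ids).to_csv(out_dir / "barcodes.tsv", sep="\t",
                                    header=False, index=False)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_zero_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with no signal in any cell; idempotent, order-preserving."""
    if expr.normalization_tag not in (RAW_COUNTS, TPM):
        raise ValueError("filter genes before log normalization")
    keep = np.flatnonzero(expr.values.sum(axis=0) > 0)
    if keep.size == 0:
        raise ValueError("all genes are zero across all cells")
    return ExpressionMatrix(expr.values[:, keep],
                            [expr.gene_ids[i] for i in keep],
                            expr.cell_ids, expr.normalization_tag)


def counts_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale raw counts to counts-per-million, used as a TPM surrogate.

    Droplet (UMI) data carries no transcript-length bias, so per-cell CPM is
    the appropriate stand-in for TPM.
    """
    if expr.normalization_tag == TPM:
        return expr
    if expr.normalization_tag != RAW_COUNTS:
        raise ValueError(f"cannot convert {expr.normalization_tag} to TPM")
    totals = expr.values.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        empty = [expr.cell_ids[i] for i in np.flatnonzero(totals[:, 0] == 0)]
        raise ValueError(f"cells with zero total counts: {empty[:10]}")
    logger.info("using counts-per-million as TPM surrogate (no gene-length model)")
    return ExpressionMatrix(expr.values / totals * 1e6, expr.gene_ids,
                            expr.cell_ids, TPM)


def normalize_log2_tpm1(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Transform TPM values to log2(TPM + 1)."""
    if expr.normalization_tag == LOG2_TPM1:
        raise ValueError("matrix is already log2(TPM+1)-normalized")
    if expr.normalization_tag == RAW_COUNTS:
        expr = counts_to_tpm(expr)
    return ExpressionMatrix(np.log2(expr.values + 1.0), expr.gene_ids,
                            expr.cell_ids, LOG2_TPM1)


# ---------------------------------------------------------------------------
# adjacent profiles
# ---------------------------------------------------------------------------

def compute_adjacent_profiles(expr: ExpressionMatrix,
                              channel_ids=DEFAULT_CHANNELS,
                              *, case_insensitive: bool = False) -> AdjacentProfiles:
    """Relative condition-gene expression per cell, on the simplex.

    Each cell's profile is its log2(TPM+1) expression on the condition genes
    divided by the cumulative expression over all of them. Cells expressing
    none of the condition genes get the uniform profile (1/K per channel) and
    a warning, keeping every row on the simplex.
    """
    if expr.normalization_tag != LOG2_TPM1:
        raise ValueError("adjacent profiles require log2(TPM+1)-normalized input")
    channel_ids = list(channel_ids)
    cols = expr.gene_index(channel_ids, case_insensitive=case_insensitive)
    sub = expr.values[:, cols]
    totals = sub.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        ids = [expr.cell_ids[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"{zero.sum()} cell(s) express no condition gene; assigned the "
            f"uniform profile: {ids[:10]}", stacklevel=2)
        sub = sub.copy()
        sub[zero] = 1.0
        totals = sub.sum(axis=1)
    weights = sub / totals[:, None]
    return AdjacentProfiles(weights, channel_ids, list(expr.cell_ids))


def select_variable_genes(expr: ExpressionMatrix, k: int,
                          metric: str = "variance") -> ExpressionMatrix:
    """Keep the ``k`` most variable genes, preserving their original order.

    ``metric`` is ``"variance"`` (plain per-gene variance on the current
    scale) or ``"dispersion"`` (variance / mean, undefined-mean genes rank
    last).
    """
    if not 1 <= k <= expr.n_genes:
        raise ValueError(f"k={k} out of range for {expr.n_genes} genes")
    if metric == "variance":
        score = expr.values.var(axis=0)
    elif metric == "dispersion":
        mean = expr.values.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(mean > 0, expr.values.var(axis=0) / mean, -np.inf)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # stable top-k: ties broken by original gene order
    order = np.argsort(-score, kind="stable")[:k]
    keep = np.sort(order)
    return ExpressionMatrix(expr.values[:, keep], [expr.gene_ids[i] for i in keep],
                            expr.cell_ids, expr.normalization_tag)


def cluster_adjacent_profiles(profiles: AdjacentProfiles, *, n_clusters: int | None = None,
                              method: str = "average", metric: str = "euclidean"):
    """Agglomerative clustering of adjacent profiles.

    Returns ``(labels, leaf_order)``: flat cluster labels (cut to
    ``n_clusters``; defaults to the number of channels) and the dendrogram
    leaf ordering for heatmap display. Average linkage on Euclidean distance
    by default.
    """
    if profiles.n_cells < 2:
        raise ValueError("clustering requires at least 2 cells")
    Z = linkage(profiles.weights, method=method, metric=metric)
    if n_clusters is None:
        n_clusters = min(profiles.n_channels, profiles.n_cells)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, leaves_list(Z)
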