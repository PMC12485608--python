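"""Turn raw count matrices into the node inputs of cell graphs.

The pipeline mirrors standard single-cell tokenization practice: library-size
normalization to a fixed target sum (default 10 000) followed by log1p,
highly-variable-gene selection by the Seurat dispersion statistic, sampling
of graph nodes proportional to expression, per-cell equal-frequency value
binning (bin 0 reserved for zeros), and padding into fixed-shape batches
with one slot reserved for the global cell node.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import GLOBAL_ID, PAD_ID, Vocabulary

logger = logging.getLogger("graphcell")

DEFAULT_TARGET_SUM = 10_000.0
DEFAULT_N_HVG = 10_000
DEFAULT_N_NODES = 1_200
DEFAULT_N_BINS = 51

#: metadata columns recognized on cells
META_COLUMNS = ("batch", "cell_type", "condition")


@dataclass
class ExpressionProfile:
    """One cell: vocabulary gene ids, raw counts, and (after preprocessing)
    log-normalized values."""

    gene_ids: np.ndarray
    counts: np.ndarray
    normed: np.ndarray | None = None
    cell_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.gene_ids.shape != self.counts.shape:
            raise ValueError("gene_ids and counts must have equal length")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class BinnedProfile:
    """A cell reduced to its graph nodes: gene ids, log-normalized values and
    ordinal bins (bin 0 <=> zero expression)."""

    node_gene_ids: np.ndarray
    values: np.ndarray
    bins: np.ndarray
    cell_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_gene_ids = np.asarray(self.node_gene_ids, dtype=np.int64)
        if len(np.unique(self.node_gene_ids)) != len(self.node_gene_ids):
            raise ValueError("duplicate gene within one cell")
        if not np.array_equal(self.bins == 0, np.asarray(self.values) == 0):
            raise ValueError("bin 0 is reserved for zero expression")

    def __len__(self):
        return len(self.node_gene_ids)


@dataclass
class TokenBatch:
    """Fixed-shape channel bundle for a batch of cells.

    Slot 0 of every row is the global cell node; pad slots have
    pad_mask False and are excluded from attention and losses.
    """

    gene_ids: np.ndarray      # (B, L) int, PAD_ID on pad slots, GLOBAL_ID at slot 0
    bins: np.ndarray          # (B, L) int, 0 on pad and global slots
    values: np.ndarray        # (B, L) float
    pad_mask: np.ndarray      # (B, L) bool, True on real slots (incl. global)
    lengths: np.ndarray       # (B,) original node counts (genes only)
    # filled by the graph/training layers:
    text: np.ndarray | None = None         # (B, L, d_text)
    no_text: np.ndarray | None = None      # (B, L) int
    pert_flags: np.ndarray | None = None   # (B, L) int
    mask_positions: np.ndarray | None = None  # (B, L) bool
    edge_index: np.ndarray | None = None   # (2, E) into flattened B*L slots
    edge_types: np.ndarray | None = None   # (E, 4) multi-hot

    @property
    def n_cells(self) -> int:
        return self.gene_ids.shape[0]

    @property
    def max_len(self) -> int:
        return self.gene_ids.shape[1]

    def gene_slot_mask(self) -> np.ndarray:
        """Real gene slots (pad and global excluded)."""
        m = self.pad_mask.copy()
        m[:, 0] = False
        return m


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def _profiles_from_arrays(X, gene_names, obs: pd.DataFrame, vocab: Vocabulary):
    import scipy.sparse as sp

    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    X = np.asarray(X, dtype=np.float64)
    known = np.array([g in vocab for g in gene_names])
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("dropping %d genes absent from vocabulary", n_unknown)
        warnings.warn(f"{n_unknown} gene(s) not in vocabulary were dropped")
    if not known.any():
        raise ValueError("no gene label resolves against the vocabulary")
    gene_ids = vocab.ids_of([g for g, k in zip(gene_names, known) if k])
    X = X[:, known]

    nonzero = (X > 0).sum(axis=1) >= 1
    n_empty = int((~nonzero).sum())
    if n_empty:
        logger.warning("filtering %d all-zero cells", n_empty)
        warnings.warn(f"{n_empty} all-zero cell(s) were filtered")
    X = X[nonzero]
    obs = obs.loc[nonzero] if len(obs) else obs
    if X.shape[0] == 0:
        raise ValueError("no cells left after filtering")

    profiles = []
    for i in range(X.shape[0]):
        meta = {}
        for col in META_COLUMNS:
            if col in obs.columns:
                meta[col] = obs[col].iloc[i]
        profiles.append(ExpressionProfile(gene_ids, X[i], cell_meta=meta))
    return profiles


def read_expression_matrix(path, vocab: Vocabulary, format: str | None = None):
    """Read a cell-by-gene count matrix into per-cell profiles.

    Supported formats: ``h5ad`` (AnnData) and ``mtx`` (MatrixMarket, cells as
    rows, with sibling ``genes.tsv`` and ``cells.tsv`` label files in the
    same directory). Gene labels are resolved against ``vocab``; unknown
    genes are dropped with a warning, all-zero cells are filtered.
    """
    from pathlib import Path

    path = Path(path)
    if format is None:
        format = "h5ad" if path.suffix == ".h5ad" else "mtx"
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if adata.n_obs == 0:
            raise ValueError("matrix contains zero cells")
        return _profiles_from_arrays(adata.X, list(adata.var_names),
                                     adata.obs.reset_index(drop=True), vocab)
    if format == "mtx":  # MatrixMarket with sibling label TSVs
        import scipy.io as sio

        X = sio.mmread(path).tocsr()
        if X.shape[0] == 0:
            raise ValueError("matrix contains zero cells")
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t")
        cells = pd.read_csv(path.parent / "cells.tsv", sep="\t")
        return _profiles_from_arrays(X, genes["symbol"].tolist(), cells, vocab)
    raise ValueError(f"unknown format: {format}")


def profiles_from_anndata(adata, vocab: Vocabulary):
    """In-memory counterpart of :func:`read_expression_matrix` for AnnData."""
    if adata.n_obs == 0:
        raise ValueError("matrix contains zero cells")
    return _profiles_from_arrays(adata.X, list(adata.var_names),
                                 adata.obs.reset_index(drop=True), vocab)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def normalize_and_log(p: ExpressionProfile,
                      target_sum: float = DEFAULT_TARGET_SUM) -> ExpressionProfile:
    """Scale counts so they sum to ``target_sum``, then log1p.

    ``normed[i] = log(1 + counts[i] * target_sum / sum(counts))``.
    """
    total = p.counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero cell")
    normed = np.log1p(p.counts * (target_sum / total))
    return ExpressionProfile(p.gene_ids, p.counts, normed=normed,
                             cell_meta=dict(p.cell_meta))


def normalize_dataset(profiles, target_sum: float = DEFAULT_TARGET_SUM):
    return [normalize_and_log(p, target_sum) for p in profiles]


def _dataset_matrix(profiles):
    gene_ids = profiles[0].gene_ids
    for p in profiles[1:]:
        if not np.array_equal(p.gene_ids, gene_ids):
            raise ValueError("profiles must share one gene panel")
    if any(p.normed is None for p in profiles):
        raise ValueError("profiles must be normalized first")
    X = np.stack([p.normed for p in profiles])
    return gene_ids, X


# --------------------------------------------------------------------------
# highly variable genes
# --------------------------------------------------------------------------

def seurat_dispersion(X: np.ndarray, n_mean_bins: int = 20) -> np.ndarray:
    """Normalized dispersion of each gene (Seurat flavor).

    ``X`` is log1p-normalized (cells x genes). Data are exponentiated back,
    per-gene dispersion var/mean is log-transformed, and z-scored within
    bins of log1p mean expression (at most ``n_mean_bins``; fewer on small
    panels so bins keep several genes each — this matches the reference
    implementation run with the same bin count). Bins holding a single gene
    score 1 when their dispersion is defined, by the standard convention.
    """
    n_mean_bins = max(1, min(n_mean_bins, X.shape[1] // 5))
    Xe = np.expm1(X)
    mean = Xe.mean(axis=0)
    var = Xe.var(axis=0, ddof=1)
    mean_safe = np.where(mean == 0, 1e-12, mean)
    disp = var / mean_safe
    with np.errstate(divide="ignore"):
        disp = np.where(disp == 0, np.nan, disp)
        disp = np.log(disp)
    mean_log = np.log1p(mean)

    df = pd.DataFrame({"mean": mean_log, "disp": disp})
    df["bin"] = pd.cut(df["mean"], bins=n_mean_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mean = grouped.transform("mean").to_numpy()
    bin_std = grouped.transform(lambda s: s.std(ddof=1)).to_numpy()
    # singleton bins have undefined std; convention: std := bin mean,
    # mean := 0, so a lone defined dispersion scores exactly 1
    singleton = np.isnan(bin_std)
    out_std = np.where(singleton, bin_mean, bin_std)
    out_mean = np.where(singleton, 0.0, bin_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (disp - out_mean) / out_std
    return z


def select_hvg(profiles, n_top: int) -> np.ndarray:
    """Rank genes by normalized dispersion, descending; return the top
    ``n_top`` vocabulary ids. Ties (and NaN dispersions) break toward lower
    vocabulary index. A constant matrix falls back to total-expression order.
    """
    if len(profiles) < 2:
        raise ValueError("HVG selection needs at least 2 cells")
    gene_ids, X = _dataset_matrix(profiles)
    n_genes = X.shape[1]
    if n_top > n_genes:
        warnings.warn(f"n_top={n_top} exceeds gene count {n_genes}; taking all")
        n_top = n_genes

    z = seurat_dispersion(X)
    rel_var = np.expm1(X).var(axis=0) / np.maximum(np.expm1(X).mean(axis=0), 1e-12) ** 2
    if np.all(~np.isfinite(z)) or rel_var.max() < 1e-10:
        warnings.warn("constant matrix: HVG ranking falls back to total expression")
        key = X.sum(axis=0)
    else:
        key = np.where(np.isnan(z), -np.inf, z)
    # stable sort: descending key, ties by ascending vocabulary id
    order = np.lexsort((gene_ids, -key))
    return gene_ids[order[:n_top]]


# --------------------------------------------------------------------------
# node sampling
# --------------------------------------------------------------------------

def sample_graph_nodes(p: ExpressionProfile, hvg: np.ndarray, k: int,
                       mode: str = "pretrain",
                       seed: int | np.random.Generator | None = None,
                       eps: float = 1e-6) -> np.ndarray:
    """Choose the gene nodes of a cell graph.

    ``pretrain``: candidates are the non-zero-expressed HVGs; ``downstream``:
    all HVGs. If at most ``k`` candidates exist all are returned in HVG
    order; otherwise ``k`` are drawn without replacement with probability
    proportional to log-normalized expression (plus ``eps`` for zeros in
    downstream mode).
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if p.normed is None:
        raise ValueError("profile must be normalized first")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    hvg = np.asarray(hvg, dtype=np.int64)
    pos = {g: i for i, g in enumerate(p.gene_ids)}
    cand = np.array([g for g in hvg if g in pos], dtype=np.int64)
    vals = np.array([p.normed[pos[g]] for g in cand])
    if mode == "pretrain":
        keep = vals > 0
        cand, vals = cand[keep], vals[keep]
    elif mode == "downstream":
        vals = vals + eps
    else:
        raise ValueError(f"unknown mode: {mode}")
    if len(cand) == 0:
        raise ValueError("empty candidate node set")
    if len(cand) <= k:
        return cand
    probs = vals / vals.sum()
    return rng.choice(cand, size=k, replace=False, p=probs)


# --------------------------------------------------------------------------
# value binning
# --------------------------------------------------------------------------

def bin_values(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Per-cell equal-frequency binning of non-zero values into 1..n_bins;
    zeros get the reserved bin 0. Monotone in the input values."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise ValueError("negative expression value")
    bins = np.zeros(values.shape, dtype=np.int64)
    nz = values > 0
    if nz.any():
        edges = np.quantile(values[nz], np.linspace(0, 1, n_bins + 1)[1:-1])
        bins[nz] = np.digitize(values[nz], edges, right=True) + 1
    return bins


def make_binned_profile(p: ExpressionProfile, nodes: np.ndarray,
                        n_bins: int = DEFAULT_N_BINS) -> BinnedProfile:
    """Restrict a normalized profile to its sampled nodes and bin the values."""
    pos = {g: i for i, g in enumerate(p.gene_ids)}
    vals = np.array([p.normed[pos[g]] for g in nodes])
    return BinnedProfile(np.asarray(nodes, dtype=np.int64), vals,
                         bin_values(vals, n_bins), cell_meta=dict(p.cell_meta))


# --------------------------------------------------------------------------
# tokenization / padding
# --------------------------------------------------------------------------

def tokenize_and_pad(bps, max_len: int) -> TokenBatch:
    """Pack binned profiles into fixed-shape (B, max_len) channels.

    Slot 0 holds the global cell node; profiles longer than ``max_len - 1``
    are truncated to their highest-expression nodes with a warning.
    """
    B = len(bps)
    gene_ids = np.full((B, max_len), PAD_ID, dtype=np.int64)
    bins = np.zeros((B, max_len), dtype=np.int64)
    values = np.zeros((B, max_len), dtype=np.float64)
    pad_mask = np.zeros((B, max_len), dtype=bool)
    lengths = np.zeros(B, dtype=np.int64)

    gene_ids[:, 0] = GLOBAL_ID
    pad_mask[:, 0] = True

    for i, bp in enumerate(bps):
        ids, vals, bn = bp.node_gene_ids, bp.values, bp.bins
        if len(ids) > max_len - 1:
            warnings.warn(f"profile of {len(ids)} nodes truncated to {max_len - 1} "
                          "highest-expression nodes")
            keep = np.sort(np.argsort(-vals, kind="stable")[: max_len - 1])
            ids, vals, bn = ids[keep], vals[keep], bn[keep]
        n = len(ids)
        gene_ids[i, 1:n + 1] = ids
        values[i, 1:n + 1] = vals
        bins[i, 1:n + 1] = bn
        pad_mask[i, 1:n + 1] = True
        lengths[i] = n
    return TokenBatch(gene_ids, bins, values, pad_mask, lengths)
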