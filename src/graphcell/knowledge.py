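"""Gene knowledge base and per-cell graph assembly.

The knowledge base holds the gene vocabulary, three edge sources (directed
TF->TG regulation, thresholded co-expression, chromosome neighborhood) and a
per-gene text-description vector table. A cell graph restricts the combined
edge table to the cell's sampled gene nodes, merges coincident edges into a
single edge with a multi-hot type feature, and wires a global cell node
bidirectionally to every gene node.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BinnedProfile, TokenBatch, tokenize_and_pad
from .vocab import N_SPECIAL, Vocabulary

logger = logging.getLogger("graphcell")

# edge-type channel order in the multi-hot feature
ET_TF_TG, ET_COEXPR, ET_CHROM, ET_GLOBAL = 0, 1, 2, 3
N_EDGE_TYPES = 4

DEFAULT_COEXPR_THRESHOLD = 0.6
DEFAULT_CHROM_WINDOW = 2


@dataclass
class KnowledgeBase:
    vocab: Vocabulary
    tf_tg: np.ndarray                      # (n, 2) int, directed (TF, TG)
    coexpr: np.ndarray                     # (m, 2) int, undirected, stored once
    coexpr_weights: np.ndarray             # (m,) correlation in [-1, 1]
    chrom: pd.DataFrame                    # columns gene_id, chrom, rank
    text_vectors: np.ndarray               # (n_genes, d_text)
    text_present: np.ndarray               # (n_genes,) bool
    chrom_window: int = DEFAULT_CHROM_WINDOW
    _edge_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.tf_tg = np.asarray(self.tf_tg, dtype=np.int64).reshape(-1, 2)
        self.coexpr = np.asarray(self.coexpr, dtype=np.int64).reshape(-1, 2)
        self.coexpr_weights = np.asarray(self.coexpr_weights, dtype=np.float64)
        gene_ids = set(self.vocab.gene_ids.tolist())
        for name, arr in (("tf_tg", self.tf_tg), ("coexpr", self.coexpr)):
            if arr.size and not set(arr.reshape(-1).tolist()) <= gene_ids:
                raise ValueError(f"{name} edge endpoint outside vocabulary")
        if self.coexpr_weights.size and (np.abs(self.coexpr_weights) > 1).any():
            raise ValueError("co-expression weights must lie in [-1, 1]")
        for _, grp in self.chrom.groupby("chrom"):
            if grp["rank"].duplicated().any():
                raise ValueError("duplicate ordinal rank within a chromosome")
        if self.text_vectors.shape[0] != self.vocab.n_genes:
            raise ValueError("text_vectors needs one row per vocabulary gene")

    @property
    def d_text(self) -> int:
        return self.text_vectors.shape[1]

    def text_vector_of(self, gene_id: int) -> np.ndarray:
        return self.text_vectors[gene_id - N_SPECIAL]

    def gene_gene_edges(self, window: int | None = None):
        """Merged directed edge table over the whole vocabulary.

        Returns ``(src, dst, types)`` where coincident multi-source edges
        carry a multi-hot type row. TF->TG stays directed; co-expression and
        chromosome edges are materialized in both directions.
        """
        window = self.chrom_window if window is None else window
        if window in self._edge_cache:
            return self._edge_cache[window]
        pairs: dict[tuple, np.ndarray] = {}

        def add(s, d, channel):
            key = (int(s), int(d))
            row = pairs.get(key)
            if row is None:
                row = np.zeros(N_EDGE_TYPES)
                pairs[key] = row
            row[channel] = 1.0

        for s, d in self.tf_tg:
            add(s, d, ET_TF_TG)
        for a, b in self.coexpr:
            add(a, b, ET_COEXPR)
            add(b, a, ET_COEXPR)
        for a, b in build_chromosome_edges(self, window):
            add(a, b, ET_CHROM)
            add(b, a, ET_CHROM)
        if pairs:
            keys = np.array(sorted(pairs), dtype=np.int64)
            types = np.stack([pairs[tuple(k)] for k in keys])
            out = (keys[:, 0], keys[:, 1], types)
        else:
            out = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                   np.zeros((0, N_EDGE_TYPES)))
        self._edge_cache[window] = out
        return out


# --------------------------------------------------------------------------
# edge construction
# --------------------------------------------------------------------------

def build_coexpression_edges(corr: pd.DataFrame,
                             threshold: float = DEFAULT_COEXPR_THRESHOLD):
    """Edges (i, j, r) for every unordered gene pair with corr(i, j) > threshold.

    ``corr`` is a symmetric gene-by-gene table (symbols as index/columns);
    the diagonal is ignored.
    """
    if list(corr.index) != list(corr.columns):
        raise ValueError("correlation table must have matching index and columns")
    M = corr.to_numpy(dtype=np.float64)
    if not np.allclose(M, M.T, atol=1e-8, equal_nan=True):
        raise ValueError("correlation table is not symmetric")
    genes = list(corr.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = M[iu, ju] > threshold
    return [(genes[i], genes[j], float(M[i, j]))
            for i, j in zip(iu[keep], ju[keep])]


def build_chromosome_edges(kb: KnowledgeBase, window: int = DEFAULT_CHROM_WINDOW):
    """Undirected edges between genes on the same chromosome whose ordinal
    ranks differ by at most ``window``. Genes without a position simply
    contribute no edges (their count is logged)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n_missing = kb.vocab.n_genes - kb.chrom["gene_id"].nunique()
    if n_missing > 0:
        logger.info("%d genes lack a chromosome position", n_missing)
    edges = []
    for _, grp in kb.chrom.groupby("chrom"):
        grp = grp.sort_values("rank")
        ids = grp["gene_id"].to_numpy()
        ranks = grp["rank"].to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if ranks[j] - ranks[i] <= window:
                    edges.append((int(ids[i]), int(ids[j])))
                else:
                    break
    return np.array(edges, dtype=np.int64).reshape(-1, 2)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_knowledge_base(kb: KnowledgeBase, dir_path):
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    kb.vocab.to_tsv(dir_path / "vocab.tsv")
    sym = kb.vocab.symbol_of
    pd.DataFrame({"tf": [sym(s) for s in kb.tf_tg[:, 0]],
                  "tg": [sym(d) for d in kb.tf_tg[:, 1]]}
                 ).to_csv(dir_path / "tf_tg.tsv", sep="\t", index=False)
    pd.DataFrame({"g1": [sym(a) for a in kb.coexpr[:, 0]],
                  "g2": [sym(b) for b in kb.coexpr[:, 1]],
                  "r": kb.coexpr_weights}
                 ).to_csv(dir_path / "coexpr.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": [sym(g) for g in kb.chrom["gene_id"]],
                  "chrom": kb.chrom["chrom"].to_numpy(),
                  "rank": kb.chrom["rank"].to_numpy()}
                 ).to_csv(dir_path / "chrom.tsv", sep="\t", index=False)
    np.save(dir_path / "text_vec.npy", kb.text_vectors)
    pd.DataFrame({"gene": [s for s, p in zip(kb.vocab.symbols, kb.text_present) if p]}
                 ).to_csv(dir_path / "text_genes.tsv", sep="\t", index=False)
    with open(dir_path / "kb.json", "w") as fh:
        json.dump({"chrom_window": kb.chrom_window}, fh)


def load_knowledge_base(dir_path) -> KnowledgeBase:
    """Load and validate a knowledge-base directory; edges touching unknown
    genes are dropped with their counts logged."""
    dir_path = Path(dir_path)
    vocab_path = dir_path / "vocab.tsv"
    if not vocab_path.exists():
        raise FileNotFoundError(f"missing vocabulary file: {vocab_path}")
    vocab = Vocabulary.from_tsv(vocab_path)

    def resolve_pairs(df, c1, c2):
        known = df[c1].isin(vocab.symbols) & df[c2].isin(vocab.symbols)
        n_drop = int((~known).sum())
        if n_drop:
            logger.warning("dropping %d edges with unknown genes", n_drop)
            import warnings
            warnings.warn(f"{n_drop} edge(s) referencing unknown genes dropped")
        df = df.loc[known]
        if len(df) == 0:
            return np.zeros((0, 2), dtype=np.int64), df
        pairs = np.stack([vocab.ids_of(df[c1]), vocab.ids_of(df[c2])], axis=1)
        return pairs, df

    tf_df = pd.read_csv(dir_path / "tf_tg.tsv", sep="\t")
    tf_tg, _ = resolve_pairs(tf_df, "tf", "tg")
    co_df = pd.read_csv(dir_path / "coexpr.tsv", sep="\t")
    coexpr, co_kept = resolve_pairs(co_df, "g1", "g2")
    weights = co_kept["r"].to_numpy(dtype=np.float64) if len(co_kept) else np.zeros(0)

    ch_df = pd.read_csv(dir_path / "chrom.tsv", sep="\t")
    ch_df = ch_df[ch_df["gene"].isin(vocab.symbols)]
    chrom = pd.DataFrame({"gene_id": vocab.ids_of(ch_df["gene"]),
                          "chrom": ch_df["chrom"].to_numpy(),
                          "rank": ch_df["rank"].to_numpy(dtype=np.int64)})

    text_vectors = np.load(dir_path / "text_vec.npy")
    tg = pd.read_csv(dir_path / "text_genes.tsv", sep="\t")
    present_syms = set(tg["gene"].tolist())
    text_present = np.array([s in present_syms for s in vocab.symbols])
    text_vectors = text_vectors * text_present[:, None]  # zero rows for missing

    window = DEFAULT_CHROM_WINDOW
    meta_path = dir_path / "kb.json"
    if meta_path.exists():
        window = json.load(open(meta_path)).get("chrom_window", window)
    return KnowledgeBase(vocab, tf_tg, coexpr, weights, chrom,
                         text_vectors, text_present, chrom_window=window)


# --------------------------------------------------------------------------
# cell graphs
# --------------------------------------------------------------------------

@dataclass
class CellGraph:
    """One cell as a graph. Node 0 is the global cell node; nodes 1..N carry
    the cell's gene ids, bins, values and text vectors. Edges are local node
    indices with a multi-hot type feature."""

    node_gene_ids: np.ndarray    # (N,) gene ids, global node excluded
    bins: np.ndarray             # (N,)
    values: np.ndarray           # (N,)
    text: np.ndarray             # (N, d_text)
    no_text: np.ndarray          # (N,) int flag, 1 where description missing
    edge_index: np.ndarray       # (2, E) local indices over N+1 nodes
    edge_types: np.ndarray       # (E, 4) multi-hot
    cell_meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        """Gene nodes plus the global node."""
        return len(self.node_gene_ids) + 1


def assemble_cell_graph(bp: BinnedProfile, kb: KnowledgeBase,
                        window: int | None = None) -> CellGraph:
    """Build the graph of one cell from its binned profile and the KB.

    Gene-gene edges are the knowledge-base edge table restricted to the node
    set; the global node is connected bidirectionally to every gene node
    with its own edge type.
    """
    nodes = bp.node_gene_ids
    if len(nodes) == 0:
        raise ValueError("empty node set")
    src, dst, types = kb.gene_gene_edges(window)

    slot = np.full(len(kb.vocab), -1, dtype=np.int64)
    slot[nodes] = np.arange(1, len(nodes) + 1)
    if src.size:
        keep = (slot[src] >= 0) & (slot[dst] >= 0)
        e_src, e_dst, e_types = slot[src[keep]], slot[dst[keep]], types[keep]
    else:
        e_src = e_dst = np.zeros(0, dtype=np.int64)
        e_types = np.zeros((0, N_EDGE_TYPES))

    g = np.arange(1, len(nodes) + 1)
    zeros = np.zeros(len(nodes), dtype=np.int64)
    glob_type = np.zeros((2 * len(nodes), N_EDGE_TYPES))
    glob_type[:, ET_GLOBAL] = 1.0
    edge_index = np.stack([np.concatenate([e_src, g, zeros]),
                           np.concatenate([e_dst, zeros, g])])
    edge_types = np.concatenate([e_types, glob_type])

    text = kb.text_vectors[nodes - N_SPECIAL]
    no_text = (~kb.text_present[nodes - N_SPECIAL]).astype(np.int64)
    return CellGraph(nodes, bp.bins, bp.values, text, no_text,
                     edge_index, edge_types, cell_meta=dict(bp.cell_meta))


def collate_graphs(graphs, max_len: int | None = None) -> TokenBatch:
    """Pack cell graphs into a padded TokenBatch with flattened edge indices.

    Edge indices are offset into the flattened (B * max_len) slot space so
    message passing runs over the whole batch at once.
    """
    if max_len is None:
        max_len = max(len(g.node_gene_ids) for g in graphs) + 1
    bps = [BinnedProfile(g.node_gene_ids, g.values, g.bins, g.cell_meta)
           for g in graphs]
    batch = tokenize_and_pad(bps, max_len)

    d_text = graphs[0].text.shape[1]
    B = len(graphs)
    text = np.zeros((B, max_len, d_text))
    no_text = np.ones((B, max_len), dtype=np.int64)
    no_text[:, 0] = 0  # the global node uses its own token, not the no-text flag
    edge_chunks, type_chunks = [], []
    for i, g in enumerate(graphs):
        n = len(g.node_gene_ids)
        if n > max_len - 1:
            raise ValueError("graph does not fit max_len; truncate upstream")
        text[i, 1:n + 1] = g.text
        no_text[i, 1:n + 1] = g.no_text
        edge_chunks.append(g.edge_index + i * max_len)
        type_chunks.append(g.edge_types)
    batch.text = text
    batch.no_text = no_text
    batch.edge_index = np.concatenate(edge_chunks, axis=1)
    batch.edge_types = np.concatenate(type_chunks, axis=0)
    return batch
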