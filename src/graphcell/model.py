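"""The cell-graph network: feature encoder, edge-type-conditioned message
passing, order-free transformer encoder, and pluggable decoder heads.

The encoder sums a gene-identity embedding, an expression-bin embedding, a
projected text-description vector and optional flag embeddings into one
initial state per node. Masked expression slots swap the bin embedding for a
learned MASK embedding (gene identity and text stay visible); the global
cell node uses dedicated tokens. GNN layers propagate states along typed
edges; transformer layers attend over all non-pad slots without positional
encoding, so the whole model is permutation-equivariant over gene nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .knowledge import N_EDGE_TYPES
from .preprocess import TokenBatch
from .tensor import Tensor, concat, index_add
from .vocab import N_SPECIAL

#: offsets into the bin-embedding table beyond the ordinary bins 0..n_bins
MASK_BIN_OFFSET = 1    # bin token n_bins + 1
GLOBAL_BIN_OFFSET = 2  # bin token n_bins + 2


@dataclass
class ModelConfig:
    vocab_size: int
    hidden_dim: int = 512
    n_gnn_layers: int = 3
    n_transformer_layers: int = 12
    n_heads: int = 8
    n_bins: int = 51
    d_text: int = 16
    dropout: float = 0.1
    d_ff: int | None = None                # defaults to 4 * hidden_dim
    n_cell_types: int | None = None        # enables the cell-type head
    two_step_mode: str | None = None       # '3class' | '5class'
    use_pert_flag: bool = False
    cell_embedding: str = "global"         # 'global' | 'mean'
    gating_threshold: float = 0.5          # tau for the two-step classifier

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.two_step_mode not in (None, "3class", "5class"):
            raise ValueError(f"invalid two-step mode: {self.two_step_mode}")
        if self.d_ff is None:
            self.d_ff = 4 * self.hidden_dim

    @property
    def n_direction_classes(self) -> int:
        return {"3class": 2, "5class": 4}[self.two_step_mode]


class GNNLayer(nn.Module):
    """One round of edge-type-conditioned message passing.

    Messages are W_type @ h_src, summed over the types set on each edge and
    over incoming edges; the node update is
    ``h <- LayerNorm(h + MLP([h ; sum_messages]))``.
    """

    def __init__(self, d: int, rng: np.random.Generator):
        self.type_proj = [nn.Linear(d, d, rng, bias=False) for _ in range(N_EDGE_TYPES)]
        self.mlp = nn.MLP(2 * d, d, d, rng)
        self.ln = nn.LayerNorm(d)

    def __call__(self, h: Tensor, edge_index: np.ndarray, edge_types: np.ndarray) -> Tensor:
        n_nodes = h.shape[0]
        src, dst = edge_index
        if len(src):
            h_src = h[src]  # (E, d)
            msg = None
            for t, proj in enumerate(self.type_proj):
                flags = edge_types[:, t]
                if not flags.any():
                    continue
                term = proj(h_src) * Tensor(flags[:, None])
                msg = term if msg is None else msg + term
            agg = index_add(msg, dst, n_nodes)
        else:
            agg = Tensor(np.zeros(h.shape))
        return self.ln(h + self.mlp(concat([h, agg], axis=-1)))


class CellGraphModel(nn.Module):
    """GNN + transformer over batches of cell graphs."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = config
        self.config = c
        d = c.hidden_dim
        # the vocabulary table doubles as the factorization matrix of the
        # context head; a larger init keeps it out of the lazy regime at
        # small scale
        self.gene_emb = nn.Embedding(c.vocab_size, d, rng, std=0.1)
        self.bin_emb = nn.Embedding(c.n_bins + 3, d, rng)  # bins 0..B, MASK, GLOBAL
        self.text_proj = nn.Linear(c.d_text, d, rng)
        self.no_text_emb = nn.Embedding(2, d, rng)
        self.pert_emb = nn.Embedding(2, d, rng)
        self.gnn_layers = [GNNLayer(d, rng) for _ in range(c.n_gnn_layers)]
        self.blocks = [nn.TransformerBlock(d, c.n_heads, c.d_ff, rng)
                       for _ in range(c.n_transformer_layers)]
        self.final_ln = nn.LayerNorm(d)
        self.expr_head = nn.MLP(d, d, 1, rng)
        # context head: predicts masked values from the expression-weighted
        # mean of visible-node vocabulary embeddings. Deliberately
        # projection-free: the pair affinity then has to live in the Gram
        # matrix of the table itself, which is what cosine-similarity GGI
        # recovery reads out.
        self.gene_bias = nn.parameter(np.zeros(c.vocab_size))
        if c.n_cell_types is not None:
            if c.n_cell_types < 2:
                raise ValueError("cell-type head needs >= 2 classes")
            self.type_head = nn.Linear(d, c.n_cell_types, rng)
        if c.two_step_mode is not None:
            self.change_head = nn.Linear(d, 1, rng)
            self.dir_head = nn.Linear(d, c.n_direction_classes, rng)

    # ------------------------------------------------------------- encoder
    def encode_features(self, batch: TokenBatch) -> Tensor:
        c = self.config
        if batch.bins.max() > c.n_bins:
            raise ValueError("bin index outside [0, n_bins]")
        bin_tokens = batch.bins.copy()
        if batch.mask_positions is not None:
            bin_tokens[batch.mask_positions] = c.n_bins + MASK_BIN_OFFSET
        bin_tokens[:, 0] = c.n_bins + GLOBAL_BIN_OFFSET  # global cell slot
        h = self.gene_emb(batch.gene_ids) + self.bin_emb(bin_tokens)
        if batch.text is not None:
            if batch.text.shape[-1] != c.d_text:
                raise ValueError("text vector dimension mismatch")
            h = h + self.text_proj(Tensor(batch.text))
            h = h + self.no_text_emb(batch.no_text)
        if c.use_pert_flag and batch.pert_flags is not None:
            h = h + self.pert_emb(batch.pert_flags)
        return h

    # ----------------------------------------------------------------- GNN
    def gnn_forward(self, h: Tensor, batch: TokenBatch) -> Tensor:
        if batch.edge_index is None or not self.gnn_layers:
            return h
        B, L, d = h.shape
        n_nodes = B * L
        if batch.edge_index.size and batch.edge_index.max() >= n_nodes:
            raise ValueError("dangling edge index")
        flat = h.reshape(n_nodes, d)
        for layer in self.gnn_layers:
            flat = layer(flat, batch.edge_index, batch.edge_types)
        return flat.reshape(B, L, d)

    # --------------------------------------------------------- transformer
    def transformer_forward(self, h: Tensor, pad_mask: np.ndarray,
                            training: bool = False, drop_rng=None) -> Tensor:
        if (~pad_mask).all(axis=1).any():
            raise ValueError("all-pad row in batch")
        for block in self.blocks:
            h = block(h, pad_mask, p_drop=self.config.dropout,
                      rng=drop_rng, training=training)
        return self.final_ln(h)

    def forward(self, batch: TokenBatch, training: bool = False,
                drop_rng=None) -> Tensor:
        h = self.encode_features(batch)
        h = self.gnn_forward(h, batch)
        return self.transformer_forward(h, batch.pad_mask,
                                        training=training, drop_rng=drop_rng)

    # -------------------------------------------------------------- decoders
    def decode_expression(self, node_emb: Tensor) -> Tensor:
        """One predicted log-normalized value per slot: (B, L)."""
        B, L, _ = node_emb.shape
        return self.expr_head(node_emb).reshape(B, L)

    def decode_masked_from_context(self, batch: TokenBatch) -> Tensor:
        """Context-head predictions (B, L): each node's value regressed as a
        bilinear match between its vocabulary embedding and the
        expression-weighted mean of the *visible* nodes' vocabulary
        embeddings (plus a per-gene bias). Used as a pre-training loss term;
        aligns co-expressed genes in the vocabulary table."""
        from .tensor import embedding as emb_lookup

        B, L = batch.gene_ids.shape
        vis = batch.gene_slot_mask()
        if batch.mask_positions is not None:
            vis = vis & ~batch.mask_positions
        w = batch.values * vis
        w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-9)
        gid_emb = self.gene_emb(batch.gene_ids)               # (B, L, d)
        ctx = (gid_emb * Tensor(w[:, :, None])).sum(axis=1)   # (B, d)
        q = ctx.reshape(B, 1, self.config.hidden_dim)
        bias = emb_lookup(self.gene_bias.reshape(-1, 1), batch.gene_ids)
        return (gid_emb * q).sum(axis=-1) + bias.reshape(B, L)

    def decode_cell_type(self, cell_emb: Tensor) -> Tensor:
        return self.type_head(cell_emb)

    def decode_two_step(self, node_emb: Tensor):
        """Per-gene (change logit, direction logits)."""
        B, L, _ = node_emb.shape
        return (self.change_head(node_emb).reshape(B, L),
                self.dir_head(node_emb))

    # ------------------------------------------------------------ embeddings
    def cell_embedding_from(self, node_emb: Tensor, batch: TokenBatch) -> Tensor:
        if self.config.cell_embedding == "mean":
            m = batch.gene_slot_mask().astype(np.float64)
            w = m / m.sum(axis=1, keepdims=True)
            return (node_emb * Tensor(w[:, :, None])).sum(axis=1)
        return node_emb[:, 0, :]

    def extract_cell_embedding(self, batch: TokenBatch) -> np.ndarray:
        node_emb = self.forward(batch)
        return self.cell_embedding_from(node_emb, batch).data.copy()

    def extract_gene_vocab_embeddings(self) -> np.ndarray:
        """Rows of the gene-identity table, special tokens excluded."""
        return self.gene_emb.weight.data[N_SPECIAL:].copy()


# --------------------------------------------------------------------------
# two-step gating
# --------------------------------------------------------------------------

THREE_CLASS_DIRECTIONS = ("down2", "up2")
FIVE_CLASS_DIRECTIONS = ("down5", "down2", "up2", "up5")
NO_CHANGE = "nc"


def two_step_call(change_logits: np.ndarray, dir_logits: np.ndarray,
                  mode: str, tau: float = 0.5) -> np.ndarray:
    """Gated decision: 'nc' when P(changed) < tau, else the direction argmax."""
    directions = {"3class": THREE_CLASS_DIRECTIONS,
                  "5class": FIVE_CLASS_DIRECTIONS}[mode]
    p_change = 1.0 / (1.0 + np.exp(-np.asarray(change_logits)))
    dir_idx = np.asarray(dir_logits).argmax(axis=-1)
    calls = np.array(directions, dtype=object)[dir_idx]
    calls = np.where(p_change < tau, NO_CHANGE, calls)
    return calls.astype(object)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model: CellGraphModel, path):
    """Single-file checkpoint: JSON config header plus named weight arrays."""
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(model.config)),
             **{f"w:{k}": v for k, v in state.items()})


def load_checkpoint(path) -> CellGraphModel:
    blob = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(str(blob["__config__"])))
    model = CellGraphModel(config)
    model.load_state_dict({k[2:]: blob[k] for k in blob.files if k.startswith("w:")})
    return model


def parameter_count(config: ModelConfig) -> int:
    """Deterministic parameter count for a configuration."""
    return CellGraphModel(config, seed=0).n_parameters()
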