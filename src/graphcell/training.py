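"""Masked-expression pre-training, task fine-tuning, the two-stage bulk
transfer schedule, and perturbation/knockout prediction.

Pre-training masks a fixed fraction (default 40%) of the expression values of
each input cell and regresses the masked log-normalized values from the
visible context (MSE at masked positions, averaged over cells). Fine-tuning
reuses the same loop for integration (self-supervised), adds a
cross-entropy head for annotation, a perturbation-flag conditioning scheme
for perturbation response, and a class-weighted two-step classifier for the
heavily imbalanced knockout direction task.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .knowledge import KnowledgeBase, assemble_cell_graph, collate_graphs
from .model import (CellGraphModel, ModelConfig, NO_CHANGE,
                    FIVE_CLASS_DIRECTIONS, THREE_CLASS_DIRECTIONS, two_step_call)
from .preprocess import (BinnedProfile, DEFAULT_N_BINS, ExpressionProfile,
                         make_binned_profile, sample_graph_nodes, select_hvg)
from .tensor import Tensor
from .vocab import Vocabulary

DEFAULT_MASK_RATIO = 0.4


# --------------------------------------------------------------------------
# masking
# --------------------------------------------------------------------------

@dataclass
class MaskPlan:
    mask_ratio: float
    masked_positions: np.ndarray   # indices into the cell's gene nodes
    seed: int | None = None


def make_mask_plan(bp: BinnedProfile, ratio: float = DEFAULT_MASK_RATIO,
                   seed: int | np.random.Generator | None = None) -> MaskPlan:
    """Uniform random subset of exactly round(ratio * n_eligible) nodes.

    Eligible nodes are gene nodes with observed (non-zero) expression; the
    global cell node is never maskable (it carries no expression).
    """
    if not 0 < ratio < 1:
        raise ValueError("mask ratio must lie in (0, 1)")
    eligible = np.flatnonzero(bp.values > 0)
    if len(eligible) == 0:
        raise ValueError("no eligible (expressed) nodes to mask")
    n_mask = int(round(ratio * len(eligible)))
    if n_mask == 0:
        warnings.warn("mask plan is empty (too few eligible nodes)")
        chosen = np.zeros(0, dtype=np.int64)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        chosen = np.sort(rng.choice(eligible, size=n_mask, replace=False))
    return MaskPlan(ratio, chosen, seed if isinstance(seed, int) else None)


def pretrain_loss(predictions: Tensor, targets: np.ndarray,
                  mask: np.ndarray) -> Tensor:
    """MSE over masked positions only, averaged over cells.

    ``predictions``: (B, L) Tensor; ``targets``/``mask``: (B, L) arrays.
    Cells with an empty mask contribute nothing; an all-empty mask is an
    error.
    """
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=1)
    valid = counts > 0
    if not valid.any():
        raise ValueError("empty mask in every cell")
    w = np.zeros(mask.shape)
    w[valid] = mask[valid] / counts[valid][:, None]
    w /= valid.sum()
    diff = predictions - Tensor(np.asarray(targets, dtype=np.float64))
    return (diff * diff * Tensor(w)).sum()


# --------------------------------------------------------------------------
# configuration / logging
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 2
    batch_size: int = 32
    lr: float = 1e-4
    warmup_steps: int = 20
    mask_ratio: float = DEFAULT_MASK_RATIO
    n_hvg: int = 10_000
    n_nodes: int = 1_200
    n_bins: int = DEFAULT_N_BINS
    seed: int = 0
    dropout_in_training: bool = True
    context_loss_weight: float = 1.0   # weight of the vocabulary context head
    # the factorization parameters (vocabulary table, context head) need a
    # much larger movement budget than the transformer path to reorganize
    # the table's geometry at small scale
    context_lr_mult: float = 10.0

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:12]


@dataclass
class TrainLog:
    losses: list = field(default_factory=list)
    lrs: list = field(default_factory=list)
    seed: int = 0
    config_hash: str = ""
    stages: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def smoothed(self, span: int = 20) -> np.ndarray:
        x = np.asarray(self.losses)
        if len(x) <= span:
            return x
        kernel = np.ones(span) / span
        return np.convolve(x, kernel, mode="valid")


def _check_finite(loss_value: float, step: int):
    if not np.isfinite(loss_value):
        raise RuntimeError(f"training diverged: non-finite loss at step {step}")


# --------------------------------------------------------------------------
# batch construction
# --------------------------------------------------------------------------

def _hvg_panel(profiles, tcfg: TrainConfig) -> np.ndarray:
    if len(profiles) < 2:  # dispersion undefined; use the full panel
        return profiles[0].gene_ids.copy()
    n_top = min(tcfg.n_hvg, len(profiles[0].gene_ids))
    return select_hvg(profiles, n_top)


def build_masked_batch(profiles, hvg, kb: KnowledgeBase, tcfg: TrainConfig,
                       rng: np.random.Generator):
    """Sample nodes, bin, assemble graphs, collate, and mask one batch."""
    graphs, plans = [], []
    for p in profiles:
        nodes = sample_graph_nodes(p, hvg, tcfg.n_nodes, mode="pretrain", seed=rng)
        bp = make_binned_profile(p, nodes, tcfg.n_bins)
        plans.append(make_mask_plan(bp, tcfg.mask_ratio, seed=rng))
        graphs.append(assemble_cell_graph(bp, kb))
    batch = collate_graphs(graphs, max_len=tcfg.n_nodes + 1)
    mask = np.zeros(batch.pad_mask.shape, dtype=bool)
    for i, plan in enumerate(plans):
        mask[i, plan.masked_positions + 1] = True  # +1: slot 0 is the global node
    batch.mask_positions = mask
    return batch


def build_downstream_batch(profiles, hvg, kb: KnowledgeBase, tcfg: TrainConfig,
                           rng: np.random.Generator,
                           pert_gene_ids=None):
    """All-HVG node sets with full expression values (no masking).

    Downstream tasks use every highly variable gene as a node, so the panel
    is identical (and in identical order) for every cell.

    ``pert_gene_ids``: gene ids to flag (and force-include) per batch; a
    single sequence applies to every cell.
    """
    pert_gene_ids = [] if pert_gene_ids is None else list(pert_gene_ids)
    graphs = []
    for p in profiles:
        nodes = sample_graph_nodes(p, hvg, len(hvg), mode="downstream", seed=rng)
        missing = [g for g in pert_gene_ids if g not in set(nodes.tolist())]
        if missing:  # condition genes are force-included as nodes
            nodes = np.concatenate([nodes, np.array(missing, dtype=np.int64)])
        graphs.append(assemble_cell_graph(make_binned_profile(p, nodes, tcfg.n_bins), kb))
    batch = collate_graphs(graphs, max_len=max(len(g.node_gene_ids)
                                               for g in graphs) + 1)
    if pert_gene_ids:
        flags = np.isin(batch.gene_ids, np.array(pert_gene_ids)).astype(np.int64)
        flags[~batch.pad_mask] = 0
        batch.pert_flags = flags
    return batch


def _iter_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


# --------------------------------------------------------------------------
# masked-expression training (pre-training and integration fine-tuning)
# --------------------------------------------------------------------------

def masked_training(model: CellGraphModel, profiles, kb: KnowledgeBase,
                    tcfg: TrainConfig, log: TrainLog | None = None,
                    optimizer: nn.Adam | None = None) -> TrainLog:
    """Optimizer loop over mask-and-predict steps (in-place on ``model``)."""
    if len(profiles) < 1:
        raise ValueError("need at least one cell")
    log = log or TrainLog(seed=tcfg.seed, config_hash=tcfg.hash())
    rng = np.random.default_rng(tcfg.seed)
    drop_rng = np.random.default_rng(tcfg.seed + 1)
    if optimizer is not None:
        opts = [optimizer]
    else:
        fast = {id(model.gene_emb.weight), id(model.gene_bias)}
        main_params = [p for p in model.parameters() if id(p) not in fast]
        fast_params = [p for p in model.parameters() if id(p) in fast]
        opts = [nn.Adam(main_params, lr=tcfg.lr, warmup_steps=tcfg.warmup_steps),
                nn.Adam(fast_params, lr=tcfg.lr * tcfg.context_lr_mult,
                        warmup_steps=tcfg.warmup_steps)]
    hvg = _hvg_panel(profiles, tcfg)
    step = 0
    for _ in range(tcfg.epochs):
        for idx in _iter_minibatches(len(profiles), tcfg.batch_size, rng):
            batch = build_masked_batch([profiles[i] for i in idx], hvg, kb, tcfg, rng)
            emb = model.forward(batch, training=tcfg.dropout_in_training,
                                drop_rng=drop_rng)
            pred = model.decode_expression(emb)
            loss = pretrain_loss(pred, batch.values, batch.mask_positions)
            if tcfg.context_loss_weight > 0:
                ctx_pred = model.decode_masked_from_context(batch)
                loss = loss + tcfg.context_loss_weight * pretrain_loss(
                    ctx_pred, batch.values, batch.mask_positions)
            _check_finite(loss.data.item(), step)
            model.zero_grad()
            loss.backward()
            for opt in opts:
                opt.step()
            log.losses.append(float(loss.data))
            log.lrs.append(opts[0].current_lr())
            step += 1
    return log


def pretrain(profiles, kb: KnowledgeBase, config: ModelConfig,
             tcfg: TrainConfig):
    """Masked-expression pre-training from random initialization."""
    model = CellGraphModel(config, seed=tcfg.seed)
    log = masked_training(model, profiles, kb, tcfg)
    log.stages.append("pretrain")
    return model, log


def finetune_integration(model: CellGraphModel, profiles, kb: KnowledgeBase,
                         tcfg: TrainConfig) -> TrainLog:
    """Continue self-supervised masked training on the target dataset (no
    label supervision); cell embeddings are then extracted for clustering."""
    log = masked_training(model, profiles, kb, tcfg)
    log.stages.append("finetune_integration")
    return log


def masked_heldout_metrics(model: CellGraphModel, profiles, kb: KnowledgeBase,
                           tcfg: TrainConfig, seed: int = 12345):
    """Held-out masked-prediction loss and Pearson correlation."""
    rng = np.random.default_rng(seed)
    hvg = _hvg_panel(profiles, tcfg)
    preds, targets = [], []
    total_loss, n_batches = 0.0, 0
    for start in range(0, len(profiles), tcfg.batch_size):
        chunk = profiles[start:start + tcfg.batch_size]
        batch = build_masked_batch(chunk, hvg, kb, tcfg, rng)
        pred = model.decode_expression(model.forward(batch))
        total_loss += float(pretrain_loss(pred, batch.values, batch.mask_positions).data)
        n_batches += 1
        m = batch.mask_positions
        preds.append(pred.data[m])
        targets.append(batch.values[m])
    preds, targets = np.concatenate(preds), np.concatenate(targets)
    corr = float(np.corrcoef(preds, targets)[0, 1]) if preds.std() > 0 else 0.0
    return {"loss": total_loss / n_batches, "corr": corr}


# --------------------------------------------------------------------------
# cell embeddings
# --------------------------------------------------------------------------

def embed_cells(model: CellGraphModel, profiles, kb: KnowledgeBase,
                tcfg: TrainConfig, seed: int = 0) -> np.ndarray:
    """Zero-shot (or post-fine-tuning) cell embeddings: downstream-mode
    graphs, no masking, global-node output."""
    rng = np.random.default_rng(seed)
    hvg = _hvg_panel(profiles, tcfg)
    out = []
    for start in range(0, len(profiles), tcfg.batch_size):
        chunk = profiles[start:start + tcfg.batch_size]
        batch = build_downstream_batch(chunk, hvg, kb, tcfg, rng)
        out.append(model.extract_cell_embedding(batch))
    return np.concatenate(out, axis=0)


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def _cross_entropy(logits: Tensor, y: np.ndarray,
                   class_weights: np.ndarray | None = None) -> Tensor:
    logp = nn.log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(y)), y]
    if class_weights is None:
        return -picked.mean()
    w = class_weights[y]
    return -(picked * Tensor(w / w.sum())).sum()


def finetune_annotation(model: CellGraphModel, profiles, labels,
                        kb: KnowledgeBase, tcfg: TrainConfig):
    """Supervised cell-type fine-tuning on a labeled reference set.

    Returns ``(classes, log)``; the model is updated in place. Prediction is
    closed-set over the reference label set.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        warnings.warn("single-class reference: degenerate predictor")
    if model.config.n_cell_types != len(classes):
        raise ValueError(f"model head has {model.config.n_cell_types} classes, "
                         f"reference has {len(classes)}")
    y = np.searchsorted(classes, labels)
    log = TrainLog(seed=tcfg.seed, config_hash=tcfg.hash())
    rng = np.random.default_rng(tcfg.seed)
    drop_rng = np.random.default_rng(tcfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=tcfg.lr, warmup_steps=tcfg.warmup_steps)
    hvg = _hvg_panel(profiles, tcfg)
    step = 0
    for _ in range(tcfg.epochs):
        for idx in _iter_minibatches(len(profiles), tcfg.batch_size, rng):
            batch = build_downstream_batch([profiles[i] for i in idx], hvg, kb,
                                           tcfg, rng)
            emb = model.forward(batch, training=tcfg.dropout_in_training,
                                drop_rng=drop_rng)
            logits = model.decode_cell_type(model.cell_embedding_from(emb, batch))
            loss = _cross_entropy(logits, y[idx])
            _check_finite(loss.data.item(), step)
            model.zero_grad()
            loss.backward()
            opt.step()
            log.losses.append(float(loss.data))
            log.lrs.append(opt.current_lr())
            step += 1
    log.stages.append("finetune_annotation")
    return classes, log


def predict_cell_type(model: CellGraphModel, profiles, classes,
                      kb: KnowledgeBase, tcfg: TrainConfig) -> np.ndarray:
    rng = np.random.default_rng(tcfg.seed)
    hvg = _hvg_panel(profiles, tcfg)
    preds = []
    for start in range(0, len(profiles), tcfg.batch_size):
        batch = build_downstream_batch(profiles[start:start + tcfg.batch_size],
                                       hvg, kb, tcfg, rng)
        emb = model.forward(batch)
        logits = model.decode_cell_type(model.cell_embedding_from(emb, batch))
        preds.append(logits.data.argmax(axis=1))
    return np.asarray(classes)[np.concatenate(preds)]


def linear_probe(ref_embeddings: np.ndarray, ref_labels, query_embeddings: np.ndarray):
    """Multinomial logistic probe on frozen embeddings."""
    from sklearn.linear_model import LogisticRegression

    ref_labels = np.asarray(ref_labels)
    if len(np.unique(ref_labels)) < 2:
        raise ValueError("linear probe needs at least 2 classes")
    clf = LogisticRegression(max_iter=2000)
    clf.fit(ref_embeddings, ref_labels)
    return clf.predict(query_embeddings)


# --------------------------------------------------------------------------
# perturbation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationCondition:
    """A set of perturbed genes with an order-normalized label ("A+B").

    The empty condition (label ``ctrl``) denotes the unperturbed control
    pass that defines the model's baseline output.
    """

    perturbed_genes: tuple
    label: str

    @classmethod
    def from_symbols(cls, vocab: Vocabulary, symbols) -> "PerturbationCondition":
        symbols = sorted(symbols)
        for s in symbols:
            if s not in vocab:
                raise ValueError(f"unknown gene: {s}")
        ids = tuple(vocab.id_of(s) for s in symbols)
        return cls(ids, "+".join(symbols) if symbols else "ctrl")

    @classmethod
    def from_label(cls, vocab: Vocabulary, label: str) -> "PerturbationCondition":
        parts = [p for p in label.split("+") if p and p != "ctrl"]
        return cls.from_symbols(vocab, parts)


def aggregate_pseudo_bulk(values: np.ndarray, conditions) -> tuple:
    """Per-gene mean over all cells sharing a condition.

    Returns ``(sorted unique condition labels, (C, G) mean matrix)``;
    invariant to cell order.
    """
    values = np.asarray(values, dtype=np.float64)
    conditions = np.asarray(conditions)
    if len(conditions) != len(values):
        raise ValueError("one condition label per cell required")
    uniq = np.unique(conditions)
    means = np.stack([values[conditions == c].mean(axis=0) for c in uniq])
    return uniq, means


def finetune_perturbation(model: CellGraphModel, control_profiles,
                          condition_targets: dict, kb: KnowledgeBase,
                          tcfg: TrainConfig) -> TrainLog:
    """Supervised perturbation fine-tuning.

    ``condition_targets``: {PerturbationCondition: (n_c, G) matrix of
    post-perturbation log-normalized values on the full gene panel}. Each
    training example pairs a control cell (input, with the condition genes
    flagged) with one perturbed profile (MSE target on the gene nodes).
    """
    if not model.config.use_pert_flag:
        raise ValueError("model must be configured with use_pert_flag=True")
    log = TrainLog(seed=tcfg.seed, config_hash=tcfg.hash())
    rng = np.random.default_rng(tcfg.seed)
    drop_rng = np.random.default_rng(tcfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=tcfg.lr, warmup_steps=tcfg.warmup_steps)
    hvg = _hvg_panel(control_profiles, tcfg)
    gene_panel = control_profiles[0].gene_ids
    col_of = {g: i for i, g in enumerate(gene_panel)}

    examples = [(cond, row) for cond, mat in condition_targets.items()
                for row in np.asarray(mat, dtype=np.float64)]
    step = 0
    for _ in range(tcfg.epochs):
        for idx in _iter_minibatches(len(examples), tcfg.batch_size, rng):
            # one condition per minibatch keeps the flag channel homogeneous
            by_cond: dict = {}
            for i in idx:
                by_cond.setdefault(examples[i][0], []).append(examples[i][1])
            for cond, targets in by_cond.items():
                ctrl = [control_profiles[rng.integers(len(control_profiles))]
                        for _ in targets]
                batch = build_downstream_batch(ctrl, hvg, kb, tcfg, rng,
                                               pert_gene_ids=cond.perturbed_genes)
                tgt = np.zeros(batch.values.shape)
                gmask = batch.gene_slot_mask()
                for r, trow in enumerate(targets):
                    cols = [col_of[g] for g in batch.gene_ids[r][gmask[r]]]
                    tgt[r, gmask[r]] = trow[cols]
                emb = model.forward(batch, training=tcfg.dropout_in_training,
                                    drop_rng=drop_rng)
                pred = model.decode_expression(emb)
                loss = pretrain_loss(pred, tgt, gmask)
                _check_finite(loss.data.item(), step)
                model.zero_grad()
                loss.backward()
                opt.step()
                log.losses.append(float(loss.data))
                log.lrs.append(opt.current_lr())
                step += 1
    log.stages.append("finetune_perturbation")
    return log


def predict_perturbation(model: CellGraphModel, control_profiles,
                         cond: PerturbationCondition, kb: KnowledgeBase,
                         tcfg: TrainConfig, seed: int = 0):
    """Predicted post-perturbation expression, averaged over control cells.

    Returns ``(gene_ids, mean predicted log-normalized values)`` on the
    node panel. An empty condition is the model's control output, so the
    predicted change of the empty condition is zero by definition.
    """
    hvg = _hvg_panel(control_profiles, tcfg)
    sums = None
    count = 0
    gene_ids_ref = None
    for start in range(0, len(control_profiles), tcfg.batch_size):
        chunk = control_profiles[start:start + tcfg.batch_size]
        batch = build_downstream_batch(chunk, hvg, kb, tcfg,
                                       np.random.default_rng(seed),
                                       pert_gene_ids=cond.perturbed_genes or None)
        if model.config.use_pert_flag and batch.pert_flags is None:
            batch.pert_flags = np.zeros(batch.gene_ids.shape, dtype=np.int64)
        pred = model.decode_expression(model.forward(batch)).data
        gmask = batch.gene_slot_mask()
        if gene_ids_ref is None:
            gene_ids_ref = batch.gene_ids[0][gmask[0]]
            sums = np.zeros(len(gene_ids_ref))
        for r in range(len(chunk)):
            assert np.array_equal(batch.gene_ids[r][gmask[r]], gene_ids_ref)
            sums += pred[r][gmask[r]]
            count += 1
    return gene_ids_ref, sums / count


# --------------------------------------------------------------------------
# knockout: labels, fine-tuning, prediction, two-stage transfer
# --------------------------------------------------------------------------

def label_knockout_genes(before: np.ndarray, after: np.ndarray,
                         mode: str = "3class") -> np.ndarray:
    """Fold-change classes with pseudocount 1: fold = (after+1)/(before+1).

    3-class: up2 (fold >= 2), down2 (fold <= 1/2), else nc. 5-class adds
    up5 (>= 5) and down5 (<= 1/5) tiers, boundaries inclusive on the
    extreme class.
    """
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    if (before < 0).any() or (after < 0).any():
        raise ValueError("negative expression")
    fold = (after + 1.0) / (before + 1.0)
    out = np.full(fold.shape, NO_CHANGE, dtype=object)
    if mode == "3class":
        out[fold >= 2] = "up2"
        out[fold <= 0.5] = "down2"
    elif mode == "5class":
        out[fold >= 2] = "up2"
        out[fold >= 5] = "up5"
        out[fold <= 0.5] = "down2"
        out[fold <= 0.2] = "down5"
    else:
        raise ValueError(f"invalid mode: {mode}")
    return out


def _knockout_batch(model, profile: ExpressionProfile, ko_genes, hvg,
                    kb: KnowledgeBase, tcfg: TrainConfig,
                    rng: np.random.Generator):
    """Direct pseudo-bulk input: one profile as a single cell, knocked-out
    genes flagged and their input expression forced to zero."""
    batch = build_downstream_batch([profile], hvg, kb, tcfg, rng,
                                   pert_gene_ids=list(ko_genes))
    ko = np.isin(batch.gene_ids, np.asarray(list(ko_genes)))
    batch.values[ko] = 0.0
    batch.bins[ko] = 0
    return batch


def finetune_knockout(model: CellGraphModel, dataset, kb: KnowledgeBase,
                      tcfg: TrainConfig, mode: str = "3class") -> TrainLog:
    """Two-step classifier fine-tuning on bulk knockout data.

    ``dataset``: iterable of (before ExpressionProfile, ko gene-id list,
    per-gene label array aligned to the profile's gene panel). Both heads
    use inverse-frequency class weights to counter the severe imbalance.
    """
    if model.config.two_step_mode != mode:
        raise ValueError("model two_step_mode does not match the label mode")
    directions = list({"3class": THREE_CLASS_DIRECTIONS,
                       "5class": FIVE_CLASS_DIRECTIONS}[mode])
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty knockout dataset")
    # inverse-frequency weights over the whole training set
    all_labels = np.concatenate([lab for _, _, lab in dataset])
    p_changed = max((all_labels != NO_CHANGE).mean(), 1e-6)
    bce_pos_w = (1 - p_changed) / p_changed
    dir_counts = np.array([(all_labels == d).sum() for d in directions], dtype=float)
    dir_w = 1.0 / np.maximum(dir_counts, 1.0)

    log = TrainLog(seed=tcfg.seed, config_hash=tcfg.hash())
    rng = np.random.default_rng(tcfg.seed)
    drop_rng = np.random.default_rng(tcfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=tcfg.lr, warmup_steps=tcfg.warmup_steps)
    profiles = [p for p, _, _ in dataset]
    hvg = _hvg_panel(profiles, tcfg)
    panel = {g: i for i, g in enumerate(profiles[0].gene_ids)}
    step = 0
    for _ in range(tcfg.epochs):
        for i in rng.permutation(len(dataset)):
            profile, ko_genes, labels = dataset[i]
            batch = _knockout_batch(model, profile, ko_genes, hvg, kb, tcfg, rng)
            emb = model.forward(batch, training=tcfg.dropout_in_training,
                                drop_rng=drop_rng)
            change_logits, dir_logits = model.decode_two_step(emb)
            gmask = batch.gene_slot_mask()
            cols = np.array([panel[g] for g in batch.gene_ids[0][gmask[0]]])
            lab = labels[cols]
            changed = (lab != NO_CHANGE).astype(np.float64)

            z = change_logits[0, 1:len(cols) + 1]
            # weighted binary cross-entropy via softplus:
            #   l = w * [softplus(z) - y*z], w = pos_weight on positives
            wts = np.where(changed == 1.0, bce_pos_w, 1.0)
            softplus = (1.0 + z.exp()).log()
            bce = ((softplus - z * Tensor(changed)) * Tensor(wts / wts.sum())).sum()

            loss = bce
            ch_idx = np.flatnonzero(changed)
            if len(ch_idx):
                y_dir = np.array([directions.index(l) for l in lab[ch_idx]])
                dlog = dir_logits[0, ch_idx + 1, :]
                loss = loss + _cross_entropy(dlog, y_dir, class_weights=dir_w)
            _check_finite(loss.data.item(), step)
            model.zero_grad()
            loss.backward()
            opt.step()
            log.losses.append(float(loss.data))
            log.lrs.append(opt.current_lr())
            step += 1
    log.stages.append("finetune_knockout")
    return log


def predict_knockout(model: CellGraphModel, profile: ExpressionProfile,
                     ko_genes, hvg_source, kb: KnowledgeBase,
                     tcfg: TrainConfig, tau: float | None = None):
    """Per-gene class calls for one knockout condition.

    Returns ``(gene_ids, calls)`` over the node panel.
    """
    rng = np.random.default_rng(tcfg.seed)
    hvg = _hvg_panel(hvg_source, tcfg)
    batch = _knockout_batch(model, profile, ko_genes, hvg, kb, tcfg, rng)
    emb = model.forward(batch)
    change_logits, dir_logits = model.decode_two_step(emb)
    gmask = batch.gene_slot_mask()
    tau = model.config.gating_threshold if tau is None else tau
    calls = two_step_call(change_logits.data[0][gmask[0]],
                          dir_logits.data[0][gmask[0]],
                          mode=model.config.two_step_mode, tau=tau)
    return batch.gene_ids[0][gmask[0]], calls


def two_stage_transfer(config: ModelConfig, kb: KnowledgeBase,
                       sc_profiles, bulk_profiles, knockout_dataset,
                       tcfg_sc: TrainConfig, tcfg_bulk: TrainConfig,
                       tcfg_ko: TrainConfig,
                       stages=("sc", "bulk", "ko"), mode: str = "3class"):
    """Single-cell masked pretrain -> bulk masked pretrain -> supervised
    knockout fine-tune; any stage can be skipped for ablation."""
    stages = list(stages)
    if not stages:
        raise ValueError("empty stage list")
    unknown = set(stages) - {"sc", "bulk", "ko"}
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    model = CellGraphModel(config, seed=tcfg_sc.seed)
    log = TrainLog(seed=tcfg_sc.seed, config_hash=tcfg_sc.hash())
    if "sc" in stages:
        masked_training(model, sc_profiles, kb, tcfg_sc, log=log)
        log.stages.append("sc_pretrain")
    if "bulk" in stages:
        masked_training(model, bulk_profiles, kb, tcfg_bulk, log=log)
        log.stages.append("bulk_pretrain")
    if "ko" in stages:
        ko_log = finetune_knockout(model, knockout_dataset, kb, tcfg_ko, mode=mode)
        log.losses.extend(ko_log.losses)
        log.lrs.extend(ko_log.lrs)
        log.stages.append("knockout_finetune")
    return model, log
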