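"""Evaluation suites: integration clustering score, gene-classification CV,
gene-gene interaction recovery, gene programs, perturbation metrics, and
knockout classification metrics.

Conventions follow the single-cell integration benchmarking (scIB) family:
Leiden clustering of a cosine kNN graph scored by NMI/ARI against cell
types, batch-ASW and graph connectivity for batch mixing, and their
unweighted mean as the overall integration score. Gene-gene interactions
are recovered by ranking cosine similarities of L2-normalized gene
embeddings and scored with the early precision ratio (EPR; 1 = random) and
the area under the precision-recall curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import NO_CHANGE

KNOCKOUT_CLASS_ORDER = ("down5", "down2", NO_CHANGE, "up2", "up5")


@dataclass
class MetricsReport:
    values: dict = field(default_factory=dict)
    per_class: dict = field(default_factory=dict)
    per_condition: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    matrices: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def to_dict(self) -> dict:
        return {"values": self.values, "per_class": self.per_class,
                "per_condition": self.per_condition, "config": self.config,
                "matrices": {k: np.asarray(v).tolist()
                             for k, v in self.matrices.items()}}


INTEGRATION_METRICS = ("nmi", "ari", "asw_batch", "graph_conn")


def overall_score(values: dict) -> float:
    """Unweighted mean of the four integration metrics; order-free."""
    missing = [m for m in INTEGRATION_METRICS if m not in values]
    if missing:
        raise ValueError(f"overall score needs all four metrics; missing {missing}")
    return float(np.mean([values[m] for m in INTEGRATION_METRICS]))


# --------------------------------------------------------------------------
# clustering / integration
# --------------------------------------------------------------------------

def _knn_adjacency(emb: np.ndarray, k: int):
    from sklearn.neighbors import kneighbors_graph

    A = kneighbors_graph(emb, n_neighbors=k, metric="cosine", mode="connectivity")
    return ((A + A.T) > 0).astype(np.int8)


def leiden_clusters(emb: np.ndarray, k: int = 15, resolution: float | None = 1.0,
                    seed: int = 0) -> np.ndarray:
    """Leiden community detection on the cosine kNN graph of an embedding.

    ``resolution=None`` uses the resolution-free modularity objective.
    """
    import igraph as ig
    import leidenalg

    A = _knn_adjacency(emb, k).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(A.row, A.col) if i < j]
    g = ig.Graph(n=emb.shape[0], edges=edges)
    if resolution is None:
        part = leidenalg.find_partition(g, leidenalg.ModularityVertexPartition,
                                        seed=seed)
    else:
        part = leidenalg.find_partition(g, leidenalg.RBConfigurationVertexPartition,
                                        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def clustering_metrics(emb: np.ndarray, cell_types, batches,
                       k: int = 15, resolution: float | None = None,
                       seed: int = 0) -> MetricsReport:
    """Four-metric integration score.

    NMI and ARI compare Leiden clusters of the embedding kNN graph with the
    cell-type labels (biology conservation); batch-ASW (mean 1 - |silhouette|
    of batch labels within each type) and graph connectivity (mean per-type
    largest-connected-component fraction of the kNN graph) measure batch
    mixing. ``overall`` is their unweighted mean.

    By the scIB convention, when ``resolution`` is None the Leiden
    resolution is scanned over 0.1..2.0 and the clustering with the best
    NMI is kept (ARI is reported for the same clustering).
    """
    from scipy.sparse.csgraph import connected_components
    from sklearn.metrics import (adjusted_rand_score,
                                 normalized_mutual_info_score,
                                 silhouette_samples)

    emb = np.asarray(emb, dtype=np.float64)
    cell_types = np.asarray(cell_types)
    batches = np.asarray(batches)
    if len(np.unique(cell_types)) < 2 or len(np.unique(batches)) < 2:
        raise ValueError("need at least 2 cell types and 2 batches")
    if k >= emb.shape[0]:
        raise ValueError("k must be smaller than the number of cells")

    resolutions = ([resolution] if resolution is not None
                   else [round(0.1 * i, 1) for i in range(1, 21)])
    nmi, ari = -1.0, 0.0
    for res in resolutions:
        clusters = leiden_clusters(emb, k=k, resolution=res, seed=seed)
        score = normalized_mutual_info_score(cell_types, clusters)
        if score > nmi:
            nmi = score
            ari = adjusted_rand_score(cell_types, clusters)

    # batch-ASW within each cell type
    asw_terms = []
    for t in np.unique(cell_types):
        sel = cell_types == t
        if len(np.unique(batches[sel])) < 2 or sel.sum() <= len(np.unique(batches[sel])):
            continue
        s = silhouette_samples(emb[sel], batches[sel])
        asw_terms.append(float(np.mean(1.0 - np.abs(s))))
    asw_batch = float(np.mean(asw_terms)) if asw_terms else float("nan")

    # graph connectivity per cell type
    A = _knn_adjacency(emb, k)
    conn_terms = []
    for t in np.unique(cell_types):
        sel = np.flatnonzero(cell_types == t)
        sub = A[sel][:, sel]
        n_comp, lab = connected_components(sub, directed=False)
        largest = np.bincount(lab).max()
        conn_terms.append(largest / len(sel))
    graph_conn = float(np.mean(conn_terms))

    values = {"nmi": float(nmi), "ari": float(ari),
              "asw_batch": asw_batch, "graph_conn": graph_conn}
    if not any(np.isnan(values[m]) for m in INTEGRATION_METRICS):
        values["overall"] = overall_score(values)
    return MetricsReport(values=values,
                         config={"k": k, "resolution": resolution, "seed": seed})


# --------------------------------------------------------------------------
# gene classification CV
# --------------------------------------------------------------------------

def gene_classification_cv(gene_embeddings: np.ndarray, labels,
                           n_folds: int = 5, seed: int = 0) -> MetricsReport:
    """Stratified k-fold CV of a logistic probe on frozen gene embeddings.

    Reports MacroF1, AUROC, AUPR and Cohen's kappa, averaged over folds.
    Folds are reduced if a class is too small to stratify.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import (average_precision_score, cohen_kappa_score,
                                 f1_score, roc_auc_score)
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(gene_embeddings, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("binary labels with >= 2 genes per class required")
    folds = min(n_folds, int(counts.min()))
    if folds < n_folds:
        warnings.warn(f"reducing folds to {folds} to keep both classes in each fold")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pos = classes[1]
    rows = []
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(max_iter=2000)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        score = clf.predict_proba(X[te])[:, list(clf.classes_).index(pos)]
        y_bin = (y[te] == pos).astype(int)
        rows.append({
            "macro_f1": f1_score(y[te], pred, average="macro"),
            "auroc": roc_auc_score(y_bin, score),
            "aupr": average_precision_score(y_bin, score),
            "kappa": cohen_kappa_score(y[te], pred),
        })
    values = {m: float(np.mean([r[m] for r in rows])) for m in rows[0]}
    return MetricsReport(values=values, config={"n_folds": folds, "seed": seed})


# --------------------------------------------------------------------------
# gene-gene interaction recovery
# --------------------------------------------------------------------------

def cosine_pair_scores(gene_embeddings: np.ndarray):
    """Cosine similarity of L2-normalized embeddings for all unordered
    gene pairs; returns (pair index arrays (i, j), scores)."""
    E = np.asarray(gene_embeddings, dtype=np.float64)
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    E = E / np.where(norms == 0, 1.0, norms)
    S = E @ E.T
    iu, ju = np.triu_indices(E.shape[0], k=1)
    return (iu, ju), S[iu, ju]


def ggi_scores(gene_embeddings: np.ndarray, true_edges) -> MetricsReport:
    """Early precision ratio and AUPR of embedding-similarity edge ranking.

    EPR = precision among the top-|truth| ranked pairs divided by the truth
    edge density (1 = random ranking). Truth edges are unordered pairs of
    gene indices into the embedding rows.
    """
    true_edges = [tuple(sorted(e)) for e in true_edges]
    if len(true_edges) < 1:
        raise ValueError("empty truth edge set")
    (iu, ju), scores = cosine_pair_scores(gene_embeddings)
    truth_set = set(true_edges)
    y = np.array([(i, j) in truth_set for i, j in zip(iu, ju)])
    if not y.any():
        raise ValueError("no truth edge lies within the gene panel")

    from sklearn.metrics import average_precision_score

    n_true = int(y.sum())
    order = np.argsort(-scores, kind="stable")
    early_precision = y[order[:n_true]].mean()
    density = n_true / len(y)
    return MetricsReport(values={
        "epr": float(early_precision / density),
        "auc_pr": float(average_precision_score(y, scores)),
        "early_precision": float(early_precision),
        "density": float(density),
    })


def extract_gene_programs(gene_embeddings: np.ndarray, k: int = 15,
                          resolution: float | None = None,
                          seed: int = 0) -> np.ndarray:
    """Cluster normalized gene embeddings into candidate gene programs
    (Leiden on the cosine kNN graph; modularity objective by default)."""
    E = np.asarray(gene_embeddings, dtype=np.float64)
    if E.shape[0] < 2:
        return np.zeros(E.shape[0], dtype=np.int64)
    if np.allclose(E, E[0]):
        warnings.warn("identical embeddings: a single degenerate program")
        return np.zeros(E.shape[0], dtype=np.int64)
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    E = E / np.where(norms == 0, 1.0, norms)
    return leiden_clusters(E, k=min(k, E.shape[0] - 1),
                           resolution=resolution, seed=seed)


# --------------------------------------------------------------------------
# perturbation metrics
# --------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def perturbation_metrics(pred: np.ndarray, truth: np.ndarray,
                         control: np.ndarray, top_n_de: int = 20
                         ) -> MetricsReport:
    """MSE / Pearson of post-perturbation values and of deltas vs control,
    over all genes and over the top-``top_n_de`` DE genes (ranked by
    |truth - control|), averaged over conditions. Undefined correlations
    (constant vectors) are reported as missing and skipped in the average.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    truth = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    control = np.asarray(control, dtype=np.float64)
    if pred.shape != truth.shape or pred.shape[1] != control.shape[0]:
        raise ValueError("pred/truth/control must share one gene panel")
    per_cond = []
    for c in range(pred.shape[0]):
        de = np.argsort(-np.abs(truth[c] - control), kind="stable")[:top_n_de]
        row = {}
        for tag, cols in (("all", slice(None)), ("de", de)):
            p, t, ctl = pred[c][cols], truth[c][cols], control[cols]
            row[f"mse_{tag}"] = float(np.mean((p - t) ** 2))
            row[f"corr_{tag}"] = _pearson(p, t)
            row[f"corr_delta_{tag}"] = _pearson(p - ctl, t - ctl)
        per_cond.append(row)
    values = {}
    for key in per_cond[0]:
        vals = np.array([r[key] for r in per_cond])
        finite = vals[np.isfinite(vals)]
        values[key] = float(finite.mean()) if len(finite) else float("nan")
    return MetricsReport(values=values,
                         per_condition={i: r for i, r in enumerate(per_cond)},
                         config={"top_n_de": top_n_de})


def direction_accuracy(pred_delta: np.ndarray, truth_delta: np.ndarray,
                       dead_zone: float = 0.05,
                       panel_sizes=(20,)) -> dict:
    """Three-way direction agreement (up / no change / down) over the
    top-k DE gene panels ranked by |truth delta|.

    A delta within ``dead_zone`` of zero is "no change". Returns
    {k: accuracy}. 2-D inputs (conditions x genes) are averaged over
    conditions.
    """
    if dead_zone < 0:
        raise ValueError("dead zone must be >= 0")
    pred_delta = np.atleast_2d(np.asarray(pred_delta, dtype=np.float64))
    truth_delta = np.atleast_2d(np.asarray(truth_delta, dtype=np.float64))

    def classify(d):
        return np.sign(d) * (np.abs(d) > dead_zone)

    out = {}
    for k in panel_sizes:
        accs = []
        for c in range(truth_delta.shape[0]):
            panel = np.argsort(-np.abs(truth_delta[c]), kind="stable")[:k]
            accs.append(np.mean(classify(pred_delta[c][panel])
                                == classify(truth_delta[c][panel])))
        out[int(k)] = float(np.mean(accs))
    return out


def ci_accuracy(pred_delta, truth_cell_deltas, levels=(0.5, 0.8, 0.95)) -> dict:
    """Fraction of predictions falling inside the t-interval of the true
    mean change, per confidence level (non-decreasing in the level).

    ``pred_delta``: (C, G) predicted mean changes; ``truth_cell_deltas``:
    per condition, an (n_c, G) matrix of per-cell true changes. Conditions
    with fewer than 2 cells are skipped with a warning.
    """
    from scipy import stats

    pred_delta = np.atleast_2d(np.asarray(pred_delta, dtype=np.float64))
    hits = {float(lv): [] for lv in levels}
    for c, cells in enumerate(truth_cell_deltas):
        cells = np.asarray(cells, dtype=np.float64)
        n = cells.shape[0]
        if n < 2:
            warnings.warn(f"condition {c} has a single cell; skipped")
            continue
        m = cells.mean(axis=0)
        se = cells.std(axis=0, ddof=1) / np.sqrt(n)
        for lv in levels:
            half = stats.t.ppf(0.5 + lv / 2.0, df=n - 1) * se
            hits[float(lv)].append(np.abs(pred_delta[c] - m) <= half)
    if not hits[float(levels[0])]:
        raise ValueError("no condition has >= 2 truth cells")
    return {lv: float(np.concatenate(h).mean()) for lv, h in hits.items()}


# --------------------------------------------------------------------------
# knockout classification metrics
# --------------------------------------------------------------------------

def knockout_metrics(pred_classes, true_classes,
                     de_mask: np.ndarray | None = None) -> MetricsReport:
    """Overall accuracy, per-class precision/recall, MacroF1, DE-gene
    accuracy (restricted to genes whose true class is not 'nc'), and the
    absolute plus row-normalized confusion matrices."""
    from sklearn.metrics import (confusion_matrix, f1_score,
                                 precision_recall_fscore_support)

    pred = np.asarray(pred_classes, dtype=object).reshape(-1)
    true = np.asarray(true_classes, dtype=object).reshape(-1)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    scheme = [c for c in KNOCKOUT_CLASS_ORDER
              if c in set(true) | set(pred)]
    stray = (set(pred) | set(true)) - set(KNOCKOUT_CLASS_ORDER)
    if stray:
        raise ValueError(f"labels outside the class scheme: {stray}")
    if de_mask is None:
        de_mask = true != NO_CHANGE
    de_mask = np.asarray(de_mask, dtype=bool).reshape(-1)

    acc = float((pred == true).mean())
    de_acc = float((pred[de_mask] == true[de_mask]).mean()) if de_mask.any() else float("nan")
    prec, rec, _, _ = precision_recall_fscore_support(
        true, pred, labels=scheme, zero_division=0)
    macro_f1 = float(f1_score(true, pred, labels=scheme, average="macro",
                              zero_division=0))
    cm = confusion_matrix(true, pred, labels=scheme)
    with np.errstate(invalid="ignore"):
        cm_norm = cm / cm.sum(axis=1, keepdims=True)
    # changed-gene recall: truly-changed genes detected as changed at all
    changed = true != NO_CHANGE
    de_recall = float((pred[changed] != NO_CHANGE).mean()) if changed.any() else float("nan")
    values = {"accuracy": acc, "de_accuracy": de_acc, "macro_f1": macro_f1,
              "de_recall": de_recall}
    per_class = {c: {"precision": float(p), "recall": float(r)}
                 for c, p, r in zip(scheme, prec, rec)}
    return MetricsReport(values=values, per_class=per_class,
                         config={"classes": scheme},
                         matrices={"confusion": cm, "confusion_norm": cm_norm})
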