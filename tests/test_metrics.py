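"""Metric suites vs independent brute-force oracles on small fixtures."""

import numpy as np
import pytest

import graphcell as gc
from graphcell.metrics import INTEGRATION_METRICS, overall_score
from oracle_utils import ari_oracle, kappa_oracle, nmi_oracle


# ------------------------------------------------------- clustering metrics

def test_constructed_optimum_scores_perfectly():
    """Three tight, well-separated type blobs, each mixing two batches."""
    rng = np.random.default_rng(0)
    centers = np.eye(3) * 50
    emb = np.concatenate([centers[i] + rng.normal(0, 0.1, size=(40, 3))
                          for i in range(3)])
    types = np.repeat(["a", "b", "c"], 40)
    batches = np.tile(["x", "y"], 60)
    rep = gc.clustering_metrics(emb, types, batches, k=10, seed=0)
    assert rep["nmi"] == pytest.approx(1.0)
    assert rep["ari"] == pytest.approx(1.0)
    assert rep["graph_conn"] == pytest.approx(1.0)
    assert rep["asw_batch"] > 0.8
    assert "overall" in rep.values


def test_overall_score_arithmetic_and_order_invariance():
    vals = {"nmi": 0.8, "ari": 0.6, "asw_batch": 0.7, "graph_conn": 0.9}
    assert overall_score(vals) == pytest.approx(0.75)
    shuffled = dict(reversed(list(vals.items())))
    assert overall_score(shuffled) == overall_score(vals)
    with pytest.raises(ValueError, match="missing"):
        overall_score({"nmi": 1.0})


def test_nmi_ari_match_contingency_oracle():
    from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

    rng = np.random.default_rng(1)
    a = rng.integers(0, 4, 30)
    b = rng.integers(0, 3, 30)
    assert normalized_mutual_info_score(a, b) == pytest.approx(nmi_oracle(a, b))
    assert adjusted_rand_score(a, b) == pytest.approx(ari_oracle(a, b))


def test_clustering_metrics_preconditions():
    emb = np.random.default_rng(0).normal(size=(30, 4))
    with pytest.raises(ValueError):
        gc.clustering_metrics(emb, ["a"] * 30, ["x", "y"] * 15)
    with pytest.raises(ValueError):
        gc.clustering_metrics(emb, ["a", "b"] * 15, ["x", "y"] * 15, k=30)


# ------------------------------------------------- gene classification CV

def test_separable_labels_score_perfectly():
    rng = np.random.default_rng(2)
    emb = np.concatenate([rng.normal(-5, 0.3, (20, 4)), rng.normal(5, 0.3, (20, 4))])
    labels = np.array([0] * 20 + [1] * 20)
    rep = gc.gene_classification_cv(emb, labels, n_folds=5, seed=0)
    assert rep["macro_f1"] == pytest.approx(1.0)
    assert rep["kappa"] == pytest.approx(1.0)
    assert rep["auroc"] == pytest.approx(1.0)


def test_random_embeddings_score_at_chance():
    aurocs = []
    for s in range(12):
        rng = np.random.default_rng(s)
        emb = rng.normal(size=(60, 6))
        labels = rng.integers(0, 2, 60)
        if min((labels == 0).sum(), (labels == 1).sum()) < 5:
            continue
        aurocs.append(gc.gene_classification_cv(emb, labels, seed=s)["auroc"])
    assert abs(np.mean(aurocs) - 0.5) < 0.1


def test_kappa_matches_hand_computed_confusion():
    # fixed 2x2 confusion: 20 TP, 5 FN, 10 FP, 15 TN
    truth = np.array([1] * 25 + [0] * 25)
    pred = np.concatenate([np.ones(20), np.zeros(5), np.ones(10), np.zeros(15)])
    from sklearn.metrics import cohen_kappa_score

    assert cohen_kappa_score(truth, pred) == pytest.approx(kappa_oracle(truth, pred))
    # hand value: po=0.7, pe=(0.5*0.6)+(0.5*0.4)=0.5 -> kappa=0.4
    assert kappa_oracle(truth, pred) == pytest.approx(0.4)


def test_cv_restratifies_small_classes():
    rng = np.random.default_rng(3)
    emb = rng.normal(size=(12, 3))
    labels = np.array([0] * 9 + [1] * 3)
    with pytest.warns(UserWarning, match="reducing folds"):
        rep = gc.gene_classification_cv(emb, labels, n_folds=5, seed=0)
    assert rep.config["n_folds"] == 3


# --------------------------------------------------------------------- GGI

def test_epr_worked_example():
    """4 genes, truth {A-B, C-D}; embeddings whose top-2 cosine pairs are
    {A-B, A-C}: early precision 1/2, density 2/6, EPR = 1.5."""
    emb = np.array([[1.0, 0.0],
                    [0.999, 0.045],   # B: closest to A
                    [0.99, 0.141],    # C: second closest to A
                    [0.0, 1.0]])      # D: far from everyone
    rep = gc.ggi_scores(emb, [(0, 1), (2, 3)])
    assert rep["early_precision"] == pytest.approx(0.5)
    assert rep["density"] == pytest.approx(2 / 6)
    assert rep["epr"] == pytest.approx(1.5)


def test_epr_perfect_ranking_equals_inverse_density():
    rng = np.random.default_rng(4)
    emb = np.concatenate([np.tile([10.0, 0], (2, 1)) + rng.normal(0, 0.01, (2, 2)),
                          rng.normal(0, 1, (6, 2))])
    truth = [(0, 1)]
    rep = gc.ggi_scores(emb, truth)
    n_pairs = 8 * 7 // 2
    assert rep["epr"] == pytest.approx(n_pairs / 1)


def test_epr_matches_exhaustive_pair_oracle():
    rng = np.random.default_rng(5)
    emb = rng.normal(size=(12, 5))
    truth = [(0, 3), (1, 2), (4, 7), (5, 11)]
    rep = gc.ggi_scores(emb, truth)
    # brute force: all pairs, cosine, top-|truth|
    E = emb / np.linalg.norm(emb, axis=1, keepdims=True)
    sims = {}
    for i in range(12):
        for j in range(i + 1, 12):
            sims[(i, j)] = E[i] @ E[j]
    top = sorted(sims, key=sims.get, reverse=True)[:len(truth)]
    precision = np.mean([p in set(map(tuple, truth)) for p in top])
    density = len(truth) / len(sims)
    assert rep["epr"] == pytest.approx(precision / density)


def test_epr_null_expectation_is_one():
    """EPR of random embeddings has expectation 1 (Monte Carlo)."""
    vals = []
    for s in range(50):
        rng = np.random.default_rng(s)
        emb = rng.normal(size=(20, 8))
        truth = [tuple(sorted(p)) for p in
                 rng.choice(20, size=(10, 2), replace=True) if p[0] != p[1]]
        truth = list({t for t in truth})
        if len(truth) < 2:
            continue
        vals.append(gc.ggi_scores(emb, truth)["epr"])
    assert abs(np.mean(vals) - 1.0) < 0.3


def test_empty_truth_rejected():
    with pytest.raises(ValueError):
        gc.ggi_scores(np.ones((4, 2)), [])


# ------------------------------------------------------------ gene programs

def test_planted_modules_recovered():
    rng = np.random.default_rng(6)
    emb = np.concatenate([rng.normal(5, 0.2, (15, 4)), rng.normal(-5, 0.2, (15, 4))])
    labels = gc.extract_gene_programs(emb, seed=0)
    from sklearn.metrics import adjusted_rand_score

    truth = [0] * 15 + [1] * 15
    assert adjusted_rand_score(truth, labels) >= 0.9


def test_single_gene_single_program():
    assert list(gc.extract_gene_programs(np.ones((1, 3)))) == [0]


def test_identical_embeddings_single_program_with_warning():
    with pytest.warns(UserWarning, match="identical"):
        labels = gc.extract_gene_programs(np.ones((8, 3)))
    assert len(set(labels)) == 1


def test_gene_programs_seed_stable():
    rng = np.random.default_rng(7)
    emb = rng.normal(size=(30, 5))
    a = gc.extract_gene_programs(emb, seed=3)
    b = gc.extract_gene_programs(emb, seed=3)
    np.testing.assert_array_equal(a, b)


# ----------------------------------------------------- perturbation metrics

def test_perfect_prediction_scores():
    rng = np.random.default_rng(8)
    truth = rng.normal(size=(3, 30))
    control = rng.normal(size=30)
    rep = gc.perturbation_metrics(truth, truth, control, top_n_de=5)
    assert rep["mse_all"] == 0.0
    assert rep["corr_all"] == pytest.approx(1.0)
    assert rep["corr_delta_all"] == pytest.approx(1.0)
    assert rep["mse_de"] == 0.0


def test_control_prediction_has_undefined_delta_correlation():
    control = np.arange(10.0)
    truth = control + np.random.default_rng(9).normal(0, 1, 10)
    rep = gc.perturbation_metrics(control[None, :], truth[None, :], control)
    assert np.isnan(rep["corr_delta_all"])  # pred - control is constant zero


def test_perturbation_metrics_match_loop_oracle():
    rng = np.random.default_rng(10)
    pred = rng.normal(size=(1, 10))
    truth = rng.normal(size=(1, 10))
    control = rng.normal(size=10)
    rep = gc.perturbation_metrics(pred, truth, control, top_n_de=4)

    # brute-force oracle
    mse = sum((pred[0][g] - truth[0][g]) ** 2 for g in range(10)) / 10

    def pearson(x, y):
        x, y = np.asarray(x), np.asarray(y)
        xm, ym = x - x.mean(), y - y.mean()
        return (xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum())

    assert rep["mse_all"] == pytest.approx(mse)
    assert rep["corr_all"] == pytest.approx(pearson(pred[0], truth[0]))
    assert rep["corr_delta_all"] == pytest.approx(
        pearson(pred[0] - control, truth[0] - control))
    de = sorted(range(10), key=lambda g: -abs(truth[0][g] - control[g]))[:4]
    assert rep["mse_de"] == pytest.approx(
        np.mean([(pred[0][g] - truth[0][g]) ** 2 for g in de]))


# --------------------------------------------------------- direction accuracy

def test_direction_identical_deltas_perfect():
    d = np.array([1.0, -2.0, 0.0, 0.5])
    acc = gc.direction_accuracy(d, d, dead_zone=0.05, panel_sizes=(4,))
    assert acc[4] == 1.0


def test_direction_all_zero_predictions_fail_on_moved_genes():
    truth = np.array([1.0, -1.0, 2.0, -2.0])
    pred = np.zeros(4)
    acc = gc.direction_accuracy(pred, truth, dead_zone=0.05, panel_sizes=(4,))
    assert acc[4] == 0.0


def test_direction_dead_zone_classification():
    truth = np.array([1.0, -1.0, 0.01])
    pred = np.array([2.0, -0.5, 0.0])
    acc = gc.direction_accuracy(pred, truth, dead_zone=0.05, panel_sizes=(3,))
    assert acc[3] == 1.0


# ------------------------------------------------------------- CI accuracy

def test_prediction_at_true_mean_always_inside():
    rng = np.random.default_rng(11)
    cells = [rng.normal(2.0, 1.0, size=(20, 6))]
    pred = cells[0].mean(axis=0)[None, :]
    acc = gc.ci_accuracy(pred, cells, levels=(0.5, 0.8, 0.95))
    assert all(v == 1.0 for v in acc.values())


def test_ci_accuracy_monotone_in_level():
    rng = np.random.default_rng(12)
    cells = [rng.normal(0, 1, size=(15, 8)) for _ in range(3)]
    pred = rng.normal(0, 1, size=(3, 8))
    wide = 1 - 1e-12
    acc = gc.ci_accuracy(pred, cells, levels=(0.5, 0.8, 0.95, wide))
    vals = [acc[lv] for lv in sorted(acc)]
    assert vals == sorted(vals)
    assert acc[wide] == 1.0  # the widening interval covers everything


def test_single_cell_condition_skipped_with_warning():
    cells = [np.ones((1, 4)), np.random.default_rng(13).normal(size=(5, 4))]
    with pytest.warns(UserWarning, match="single cell"):
        acc = gc.ci_accuracy(np.zeros((2, 4)), cells, levels=(0.9,))
    assert 0.0 <= acc[0.9] <= 1.0


# ----------------------------------------------------------- knockout metrics

def test_all_unchanged_baseline_on_imbalanced_truth():
    truth = np.array(["nc"] * 96 + ["up2", "up2", "down2", "down2"], dtype=object)
    pred = np.full(100, "nc", dtype=object)
    rep = gc.knockout_metrics(pred, truth)
    assert rep["accuracy"] == pytest.approx(0.96)
    assert rep["de_accuracy"] == 0.0
    assert rep["de_recall"] == 0.0


def test_perfect_prediction_identity_confusion():
    truth = np.array(["nc", "up2", "down2", "nc", "up2"], dtype=object)
    rep = gc.knockout_metrics(truth.copy(), truth)
    cm = rep.matrices["confusion"]
    assert (cm == np.diag(np.diag(cm))).all()
    assert rep["macro_f1"] == 1.0


def test_confusion_row_sums_equal_true_counts():
    rng = np.random.default_rng(14)
    classes = np.array(["nc", "up2", "down2"], dtype=object)
    truth = classes[rng.integers(0, 3, 50)]
    pred = classes[rng.integers(0, 3, 50)]
    rep = gc.knockout_metrics(pred, truth)
    cm = rep.matrices["confusion"]
    for i, c in enumerate(rep.config["classes"]):
        assert cm[i].sum() == (truth == c).sum()


def test_label_scheme_mismatch_rejected():
    with pytest.raises(ValueError, match="scheme"):
        gc.knockout_metrics(np.array(["weird"], dtype=object),
                            np.array(["nc"], dtype=object))
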