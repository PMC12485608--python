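"""Independent brute-force oracles shared by the metric and acceptance tests.

These are deliberately naive implementations (contingency tables, explicit
pair enumeration, per-element loops) kept separate from the package so the
package's metrics are checked against a second route.
"""

import numpy as np


def nmi_oracle(a, b):
    """Contingency-table NMI with arithmetic-mean normalization."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)

    def entropy(x):
        _, c = np.unique(x, return_counts=True)
        p = c / n
        return -(p * np.log(p)).sum()

    mi = 0.0
    for u in np.unique(a):
        for v in np.unique(b):
            p_uv = ((a == u) & (b == v)).mean()
            if p_uv > 0:
                mi += p_uv * np.log(p_uv / ((a == u).mean() * (b == v).mean()))
    denom = (entropy(a) + entropy(b)) / 2
    return mi / denom if denom > 0 else 1.0


def ari_oracle(a, b):
    """Pair-counting adjusted Rand index."""
    from math import comb

    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    sum_ij = sum(comb(int(((a == u) & (b == v)).sum()), 2)
                 for u in np.unique(a) for v in np.unique(b))
    sum_a = sum(comb(int((a == u).sum()), 2) for u in np.unique(a))
    sum_b = sum(comb(int((b == v).sum()), 2) for v in np.unique(b))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


def kappa_oracle(y1, y2):
    y1, y2 = np.asarray(y1), np.asarray(y2)
    po = (y1 == y2).mean()
    pe = sum((y1 == c).mean() * (y2 == c).mean()
             for c in np.unique(np.concatenate([y1, y2])))
    return (po - pe) / (1 - pe)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def epr_oracle(embeddings, truth):
    """Exhaustive pair ranking: precision among the top-|truth| cosine pairs
    over the truth edge density."""
    E = np.asarray(embeddings, float)
    E = E / np.linalg.norm(E, axis=1, keepdims=True)
    sims = {}
    n = E.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            sims[(i, j)] = float(E[i] @ E[j])
    truth_set = {tuple(sorted(t)) for t in truth}
    top = sorted(sims, key=sims.get, reverse=True)[:len(truth_set)]
    precision = np.mean([p in truth_set for p in top])
    density = len(truth_set) / len(sims)
    return precision / density


def aupr_oracle(y, scores):
    """Step-wise area under the precision-recall curve."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(y)[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    return float((precision * y).sum() / y.sum())
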