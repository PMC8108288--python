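"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each statistic from its definition by
enumeration or exhaustive sweeps; they never call the code paths they
check.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def bh_stepup_brute(pvalues):
    """Benjamini-Hochberg step-up from the definition.

    Sort ascending, compute p_(i) * n / i, enforce monotonicity from the
    largest rank down, cap at 1, return in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    adj = np.empty(n)
    adj[order] = np.minimum(scaled, 1.0)
    return adj


def wilcoxon_signflip_brute(x, y):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Requires no zero differences and no ties in |d|.  Two-sided p is
    2 * min(P(W+ <= w), P(W+ >= w)) capped at 1, the exact-distribution
    convention.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [np.sum(ranks[list(signs)]) if signs else 0.0
         for r in range(n + 1)
         for signs in itertools.combinations(range(n), r)]
    )
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def average_precision_brute(scores, labels):
    """AP by sweeping every distinct threshold of the score vector.

    At each threshold t (descending) predict positive where score >= t;
    AP = sum of (recall step) x (precision at that threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = float(y[pred].sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def leading_eigvec_eigengene(expr, genes):
    """Module eigengene via the leading eigenvector of the gene-gene
    correlation matrix: per-sample scores z.T @ u, unit-normalised and
    sign-oriented to positive mean gene correlation."""
    sub = expr.loc[list(genes)].to_numpy(dtype=float)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=0)[:, None]
    corr = np.corrcoef(z)
    vals, vecs = np.linalg.eigh(corr)
    u = vecs[:, -1]
    scores = z.T @ u
    scores = scores / np.linalg.norm(scores)
    if np.mean(z @ scores) < 0:
        scores = -scores
    return scores
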