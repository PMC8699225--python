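"""Independent brute-force oracles used to check the fast implementations.

Everything here is written element-by-element from the defining formulas,
deliberately avoiding the matrix formulations used inside the package.
"""

import numpy as np


def brute_vanraden(W, ploidy, policy="ploidy_scaled"):
    """Element-by-element centered cross-product GRM."""
    W = np.asarray(W, float)
    n, m = W.shape
    p = W.mean(axis=0) / ploidy
    c = (ploidy if policy == "ploidy_scaled" else 2.0) * sum(
        p[i] * (1 - p[i]) for i in range(m)
    )
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(m):
                acc += (W[j, i] - ploidy * p[i]) * (W[k, i] - ploidy * p[i])
            G[j, k] = acc / c
    return G


def brute_weighted(W, ploidy, weights, policy="ploidy_scaled", mean_one=True):
    W = np.asarray(W, float)
    w = np.asarray(weights, float)
    if mean_one:
        w = w / w.mean()
    n, m = W.shape
    p = W.mean(axis=0) / ploidy
    c = (ploidy if policy == "ploidy_scaled" else 2.0) * sum(
        p[i] * (1 - p[i]) for i in range(m)
    )
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(m):
                acc += w[i] * (W[j, i] - ploidy * p[i]) * (W[k, i] - ploidy * p[i])
            G[j, k] = acc / c
    return G


def brute_yang(W):
    """Per-element diploid GRM with distinct diagonal/off-diagonal forms."""
    W = np.asarray(W, float)
    n, N = W.shape
    p = W.mean(axis=0) / 2.0
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(N):
                d = 2.0 * p[i] * (1 - p[i])
                if j == k:
                    acc += (W[j, i] ** 2 - (1 + 2 * p[i]) * W[j, i] + 2 * p[i] ** 2) / d
                else:
                    acc += (W[j, i] - 2 * p[i]) * (W[k, i] - 2 * p[i]) / d
            G[j, k] = acc / N + (1.0 if j == k else 0.0)
    return G


def brute_slater(dosages):
    """Full-autotetraploid GRM from hand-built genotype-class indicators."""
    dos = np.asarray(dosages, int)
    n, m = dos.shape
    cols = []  # (indicator column, class frequency)
    for i in range(m):
        for cls in range(5):
            x = (dos[:, i] == cls).astype(float)
            f = x.mean()
            if 0 < f < 1:
                cols.append((x, f))
    M = 5 * m
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for x, f in cols:
                acc += (x[j] - f) * (x[k] - f) / (f * (1 - f))
            G[j, k] = 1.0 + acc / M
    return G


def brute_reml_grid(y, X, K, lo=-6.0, hi=6.0, step=0.001):
    """Dense grid search of the restricted likelihood in log delta.

    Evaluates the REML criterion directly from determinants and GLS
    residuals at every grid point — no eigendecomposition shortcut —
    and returns the maximizing log delta.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    K = np.asarray(K, float)
    n, q = X.shape
    grid = np.arange(lo, hi + step / 2, step)
    best, best_ll = None, -np.inf
    for g in grid:
        delta = np.exp(g)
        V = K + delta * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = float(r @ Vi @ r) / (n - q)
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XtViX)
        ll = -0.5 * ((n - q) * np.log(s2) + ldV + ldX + (n - q))
        if ll > best_ll:
            best, best_ll = g, ll
    return best


def pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))
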