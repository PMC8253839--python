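"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (loops, enumeration, closed forms,
batch gradient descent) and shares no code with the implementation under
test.
"""

from __future__ import annotations

import numpy as np


def pearson_distance_direct(u, v) -> float:
    """1 - Pearson r via the covariance formula, no library call."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    uc = u - u.mean()
    vc = v - v.mean()
    return 1.0 - float((uc * vc).sum() / np.sqrt((uc**2).sum() * (vc**2).sum()))


def rdm_bruteforce(X, categories):
    """Exhaustive pairwise loop over category vectors."""
    n = len(categories)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pearson_distance_direct(X[i], X[j])
    return out


def rank_average_ties(x):
    """Average ranks, 1-based, computed by sorting."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_direct(a, b) -> float:
    """Rank both vectors (average ties) then Pearson."""
    ra = rank_average_ties(a)
    rb = rank_average_ties(b)
    return 1.0 - pearson_distance_direct(ra, rb)


def bh_bruteforce(p):
    """Benjamini-Hochberg from its definition: p*m/rank with running min."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        rank = k + 1
        running = min(running, p[order[k]] * m / rank)
        q[order[k]] = running
    return np.minimum(q, 1.0)


def softmax_cbow_fullbatch(scenes, labels, dim=5, lr=1.0, n_iter=3000, seed=0):
    """Exact full-softmax CBOW trained by batch gradient descent.

    Returns the input-side embedding matrix aligned to ``labels``.
    """
    idx = {l: i for i, l in enumerate(labels)}
    pairs = []
    for sc in scenes:
        ids = [idx[l] for l in sc]
        for t in ids:
            pairs.append(([c for c in ids if c != t], t))
    V = len(labels)
    rng = np.random.RandomState(seed)
    w_in = (rng.rand(V, dim) - 0.5) / dim
    w_out = np.zeros((V, dim))
    C = np.zeros((len(pairs), V))
    T = np.zeros(len(pairs), dtype=int)
    for k, (ctx, t) in enumerate(pairs):
        C[k, ctx] = 1.0 / len(ctx)
        T[k] = t
    for _ in range(n_iter):
        H = C @ w_in
        Z = H @ w_out.T
        Z -= Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        P[np.arange(len(T)), T] -= 1.0
        g_out = P.T @ H / len(pairs)
        g_in = C.T @ (P @ w_out) / len(pairs)
        w_in -= lr * g_in
        w_out -= lr * g_out
    return w_in


def pmi_vectors(scenes, labels):
    """Positive PMI co-occurrence vectors (one row per label)."""
    idx = {l: i for i, l in enumerate(labels)}
    V = len(labels)
    C = np.zeros((V, V))
    for sc in scenes:
        ids = [idx[l] for l in sc if l in idx]
        for i in ids:
            for j in ids:
                if i != j:
                    C[i, j] += 1
    tot = C.sum()
    pi = C.sum(axis=1) / tot
    with np.errstate(divide="ignore"):
        pmi = np.log(C / tot) - np.log(pi)[:, None] - np.log(pi)[None, :]
    pmi[~np.isfinite(pmi)] = 0.0
    return np.maximum(pmi, 0.0)


def mean_cosine_within_between(M, group_ids):
    """Mean cosine similarity within and between groups of row vectors."""
    X = M / np.linalg.norm(M, axis=1, keepdims=True)
    S = X @ X.T
    g = np.asarray(group_ids)
    n = len(g)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if g[i] == g[j] else between).append(S[i, j])
    return float(np.mean(within)), float(np.mean(between))
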