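"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive: plain loops over pairs and definitions transcribed
directly, sharing no code with the implementations they check.
"""

import itertools

import numpy as np


def auc_by_pair_counting(scores, labels) -> float:
    """P(positive outscores negative) with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total


def pairwise_distances(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(((x[i] - x[j]) ** 2).sum())
    return d


def davies_bouldin_naive(x, labels) -> float:
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    ks = sorted(set(labels.tolist()))
    cent = {c: x[labels == c].mean(axis=0) for c in ks}
    sig = {
        c: np.mean([np.linalg.norm(p - cent[c]) for p in x[labels == c]]) for c in ks
    }
    total = 0.0
    for i in ks:
        worst = 0.0
        for j in ks:
            if i == j:
                continue
            worst = max(worst, (sig[i] + sig[j]) / np.linalg.norm(cent[i] - cent[j]))
        total += worst
    return total / len(ks)


def silhouette_naive(x, labels) -> float:
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    d = pairwise_distances(x)
    ks = sorted(set(labels.tolist()))
    s = []
    for i in range(len(x)):
        own = labels[i]
        mine = [j for j in range(len(x)) if labels[j] == own and j != i]
        if not mine:
            s.append(0.0)
            continue
        a = np.mean([d[i, j] for j in mine])
        b = min(
            np.mean([d[i, j] for j in range(len(x)) if labels[j] == c])
            for c in ks
            if c != own
        )
        s.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(s))


def calinski_harabasz_naive(x, labels) -> float:
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    ks = sorted(set(labels.tolist()))
    n, k = len(x), len(ks)
    grand = x.mean(axis=0)
    w = sum(((x[labels == c] - x[labels == c].mean(axis=0)) ** 2).sum() for c in ks)
    b = sum(
        (labels == c).sum() * ((x[labels == c].mean(axis=0) - grand) ** 2).sum()
        for c in ks
    )
    return (b / (k - 1)) / (w / (n - k))


def baker_hubert_naive(x, labels) -> float:
    """Exhaustive concordant/discordant comparison of all pair-of-pairs."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    d = pairwise_distances(x)
    n = len(x)
    within, between = [], []
    for i, j in itertools.combinations(range(n), 2):
        (within if labels[i] == labels[j] else between).append(d[i, j])
    s_plus = s_minus = 0
    for w in within:
        for b in between:
            if w < b:
                s_plus += 1
            elif w > b:
                s_minus += 1
    return (s_plus - s_minus) / (s_plus + s_minus)


def hubert_levine_naive(x, labels) -> float:
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    d = pairwise_distances(x)
    n = len(x)
    within, alldist = [], []
    for i, j in itertools.combinations(range(n), 2):
        alldist.append(d[i, j])
        if labels[i] == labels[j]:
            within.append(d[i, j])
    alldist.sort()
    nw = len(within)
    s_w = sum(within)
    s_min = sum(alldist[:nw])
    s_max = sum(alldist[-nw:])
    return (s_w - s_min) / (s_max - s_min)


def lasso_coordinate_descent(x, y, penalty, n_sweeps=2000, tol=1e-12):
    """Naive cyclic coordinate descent for (1/2n)||y - Xw||^2 + λ||w||_1.

    Assumes standardized columns are NOT required; uses exact
    per-coordinate updates with the soft-threshold kernel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    w = np.zeros(p)
    col_sq = (x**2).sum(axis=0) / n
    for _ in range(n_sweeps):
        w_old = w.copy()
        for j in range(p):
            r = y - x @ w + x[:, j] * w[j]
            rho = (x[:, j] @ r) / n
            if col_sq[j] == 0:
                w[j] = 0.0
                continue
            w[j] = np.sign(rho) * max(abs(rho) - penalty, 0.0) / col_sq[j]
        if np.abs(w - w_old).max() < tol:
            break
    return w


def modularity_naive(graph, communities) -> float:
    """Newman modularity computed from the definition."""
    m = graph.number_of_edges()
    deg = dict(graph.degree())
    q = 0.0
    for comm in communities:
        comm = set(comm)
        l_c = sum(1 for u, v in graph.edges if u in comm and v in comm)
        d_c = sum(deg[v] for v in comm)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q
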