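"""Internal cluster-validity indices and the points-based ranking scheme.

Five indices are computed in feature space (Euclidean distances between
subjects' selected-feature vectors) for a given labeling:

* Davies–Bouldin (lower better): mean over clusters of the worst
  pairwise ``(σ_i + σ_j) / d(c_i, c_j)``, with ``σ`` the mean distance
  to the cluster centroid.
* Silhouette (higher better): mean of ``(b − a) / max(a, b)``;
  singleton-cluster points score 0.
* Calinski–Harabasz (higher better): the between/within variance-ratio
  ``[B/(k−1)] / [W/(n−k)]``.
* Baker–Hubert Γ (higher better): concordance between within-cluster
  and between-cluster distance pairs, ``(s⁺ − s⁻)/(s⁺ + s⁻)``.
* Hubert–Levine C (lower better): ``(S_w − S_min)/(S_max − S_min)``
  where ``S_w`` sums the within-cluster distances and ``S_min``/``S_max``
  sum the same number of globally smallest/largest distances.

Ranking gives one point per index to the best-scoring clustering; the
winner is the clustering with the most points.  Exact index ties
withhold that index's point (logged).  Points ties between clusterings
are broken by pairwise comparison across all five indices, awarding the
win to whichever takes the majority.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ScoreCard",
    "RankResult",
    "davies_bouldin",
    "silhouette",
    "calinski_harabasz",
    "baker_hubert_gamma",
    "hubert_levine_c",
    "score_partition",
    "rank",
    "INDEX_DIRECTIONS",
]

# +1: higher is better; -1: lower is better
INDEX_DIRECTIONS = {
    "davies_bouldin": -1,
    "silhouette": +1,
    "calinski_harabasz": +1,
    "baker_hubert": +1,
    "hubert_levine": -1,
}


class DegenerateClusteringError(ValueError):
    """Raised when an index is undefined for the given labeling."""


def _validate(x: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    if len(labels) != len(x):
        raise ValueError("labels must cover every row of X")
    _, labels = np.unique(labels, return_inverse=True)
    if labels.max() < 1:
        raise DegenerateClusteringError("need at least two clusters")
    return x, labels


def _within_between(dist: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    return dist[same], dist[~same]


def davies_bouldin(x: np.ndarray, labels) -> float:
    """Davies–Bouldin index; raises on coincident centroids."""
    x, labels = _validate(x, labels)
    k = labels.max() + 1
    centroids = np.stack([x[labels == c].mean(axis=0) for c in range(k)])
    sigma = np.array(
        [np.linalg.norm(x[labels == c] - centroids[c], axis=1).mean() for c in range(k)]
    )
    sep = squareform(pdist(centroids))
    ratios = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if sep[i, j] == 0:
                raise DegenerateClusteringError(
                    f"clusters {i} and {j} have coincident centroids"
                )
            ratios[i, j] = (sigma[i] + sigma[j]) / sep[i, j]
    return float(ratios.max(axis=1).mean())


def silhouette(x: np.ndarray, labels) -> float:
    """Mean silhouette width with the singleton-scores-zero convention."""
    x, labels = _validate(x, labels)
    d = squareform(pdist(x))
    if d.max() == 0:
        warnings.warn("all points identical; silhouette is 0 by convention")
        return 0.0
    n = len(labels)
    k = labels.max() + 1
    sizes = np.bincount(labels, minlength=k)
    # mean distance from each point to each cluster
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = d[:, labels == c].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue  # singleton convention: s(i) = 0
        a = sums[i, c] / (sizes[c] - 1)
        b = min(
            sums[i, o] / sizes[o] for o in range(k) if o != c and sizes[o] > 0
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def calinski_harabasz(x: np.ndarray, labels) -> float:
    """Variance-ratio criterion; +inf (flagged) at zero within-cluster scatter."""
    x, labels = _validate(x, labels)
    n = len(labels)
    k = labels.max() + 1
    if k >= n:
        raise DegenerateClusteringError("need k <= n-1 clusters")
    grand = x.mean(axis=0)
    w = 0.0
    b = 0.0
    for c in range(k):
        pts = x[labels == c]
        centroid = pts.mean(axis=0)
        w += ((pts - centroid) ** 2).sum()
        b += len(pts) * ((centroid - grand) ** 2).sum()
    if w == 0:
        warnings.warn("zero within-cluster variance; Calinski-Harabasz is infinite")
        return float("inf")
    return float((b / (k - 1)) / (w / (n - k)))


def baker_hubert_gamma(x: np.ndarray, labels) -> float:
    """Baker–Hubert Γ via sorted between-distance counting (O(N log N))."""
    x, labels = _validate(x, labels)
    within, between = _within_between(pdist(x), labels)
    if len(within) == 0 or len(between) == 0:
        raise DegenerateClusteringError("need both within- and between-cluster pairs")
    between = np.sort(between)
    # s+ : pairs with within < between ; s- : within > between
    s_plus = (len(between) - np.searchsorted(between, within, side="right")).sum()
    s_minus = np.searchsorted(between, within, side="left").sum()
    total = s_plus + s_minus
    if total == 0:
        warnings.warn("all within/between distances tie; gamma is 0")
        return 0.0
    return float((s_plus - s_minus) / total)


def hubert_levine_c(x: np.ndarray, labels) -> float:
    """Hubert–Levine C-index in [0, 1]."""
    x, labels = _validate(x, labels)
    d = pdist(x)
    within, between = _within_between(d, labels)
    if len(within) == 0 or len(between) == 0:
        raise DegenerateClusteringError("need both within- and between-cluster pairs")
    n_w = len(within)
    d_sorted = np.sort(d)
    s_w = within.sum()
    s_min = d_sorted[:n_w].sum()
    s_max = d_sorted[-n_w:].sum()
    if s_max == s_min:
        warnings.warn("degenerate distance spread; C-index is 0 by convention")
        return 0.0
    return float((s_w - s_min) / (s_max - s_min))


_INDEX_FUNCS = {
    "davies_bouldin": davies_bouldin,
    "silhouette": silhouette,
    "calinski_harabasz": calinski_harabasz,
    "baker_hubert": baker_hubert_gamma,
    "hubert_levine": hubert_levine_c,
}


@dataclass(frozen=True)
class ScoreCard:
    """The five index values for one clustering of one feature matrix."""

    clustering_id: tuple
    davies_bouldin: float
    silhouette: float
    calinski_harabasz: float
    baker_hubert: float
    hubert_levine: float

    def value(self, index: str) -> float:
        return getattr(self, index)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in INDEX_DIRECTIONS}


def score_partition(x: np.ndarray, labels, clustering_id: tuple) -> ScoreCard:
    """Compute all five indices for one labeling."""
    values = {name: fn(x, labels) for name, fn in _INDEX_FUNCS.items()}
    return ScoreCard(clustering_id=tuple(clustering_id), **values)


@dataclass
class RankResult:
    """Outcome of the points scheme over a pool of scorecards."""

    points: dict
    winner: tuple
    tiebreak_log: list = field(default_factory=list)
    withheld: list = field(default_factory=list)


def _pairwise_better(a: ScoreCard, b: ScoreCard) -> int:
    """Number of indices on which ``a`` strictly beats ``b``."""
    wins = 0
    for index, direction in INDEX_DIRECTIONS.items():
        if direction * (a.value(index) - b.value(index)) > 0:
            wins += 1
    return wins


def rank(scorecards: list[ScoreCard]) -> RankResult:
    """Award one point per index to the best clustering; break points ties.

    On an exact numeric tie for an index's best score the point is
    withheld and logged.  A points tie among leaders is resolved by
    round-robin pairwise comparison over all five indices; the leader
    with the most pairwise index wins takes the title (final fallback:
    input order, recorded in the log).
    """
    if len(scorecards) < 2:
        raise ValueError("ranking needs at least two scorecards")
    ids = [sc.clustering_id for sc in scorecards]
    if len(set(ids)) != len(ids):
        raise ValueError("clustering ids must be unique")
    points = {cid: 0 for cid in ids}
    withheld = []
    for index, direction in INDEX_DIRECTIONS.items():
        values = [sc.value(index) for sc in scorecards]
        best = max(values) if direction > 0 else min(values)
        leaders = [sc.clustering_id for sc, v in zip(scorecards, values) if v == best]
        if len(leaders) > 1:
            withheld.append({"index": index, "tied": leaders, "value": best})
        else:
            points[leaders[0]] += 1

    top = max(points.values())
    leaders = [cid for cid in ids if points[cid] == top]
    log: list = []
    if len(leaders) == 1:
        winner = leaders[0]
    else:
        by_id = {sc.clustering_id: sc for sc in scorecards}
        wins = {cid: 0 for cid in leaders}
        for i, a in enumerate(leaders):
            for b in leaders[i + 1:]:
                a_wins = _pairwise_better(by_id[a], by_id[b])
                b_wins = _pairwise_better(by_id[b], by_id[a])
                log.append({"pair": (a, b), "wins": (a_wins, b_wins)})
                if a_wins > b_wins:
                    wins[a] += 1
                elif b_wins > a_wins:
                    wins[b] += 1
        best_wins = max(wins.values())
        final = [cid for cid in leaders if wins[cid] == best_wins]
        winner = final[0]
        if len(final) > 1:
            log.append({"unresolved": final, "chose": winner})
    return RankResult(points=points, winner=winner, tiebreak_log=log, withheld=withheld)
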