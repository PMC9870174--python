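"""Subject-similarity graph inference.

Four estimators turn the positive-target submatrix into an undirected
simple graph whose nodes are subjects:

* kNN — Euclidean distances between subjects' 0/1 feature vectors; each
  subject is joined to its k nearest neighbors and the directed
  relations are unioned, so the average degree is close to (but not
  exactly) k.  Following the minimum-connectivity convention, the
  pipeline uses the smallest k whose union graph is connected.
* CT — correlation thresholding: an edge wherever the Pearson
  correlation between two subjects' response vectors exceeds a
  threshold.
* MB — Meinshausen–Bühlmann neighborhood selection: an L1-penalized
  regression of each node on all others (subjects as variables,
  features as observations); neighborhoods are combined with the OR
  rule.
* glasso — the graphical lasso: L1-penalized sparse inverse-covariance
  estimation; an edge wherever an off-diagonal precision entry is
  numerically nonzero.

Because all four assume sparse structure, :func:`sparsest_connected`
scans a monotone parameter path (descending threshold for CT, a
descending 30-point logarithmic penalty path for MB/glasso) and keeps
the sparsest graph on the path that is connected, by analogy with the
minimum-k rule for kNN.
"""

from __future__ import annotations

import warnings
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.linear_model import Lasso

from .preprocess import FeatureMatrix

__all__ = [
    "subset_positive",
    "knn_graph",
    "min_k_connected",
    "subject_correlation",
    "ct_graph",
    "mb_graph",
    "glasso_graph",
    "sparsest_connected",
    "infer_graph",
    "soft_threshold",
    "write_graph",
    "read_graph",
]

InferenceMethod = Literal["knn", "mb", "glasso", "ct"]

_EDGE_TOL = 1e-8  # |precision| / |coefficient| above this counts as an edge


def soft_threshold(z: float | np.ndarray, penalty: float) -> float | np.ndarray:
    """The lasso shrinkage kernel S(z, λ) = sign(z)·max(|z| − λ, 0)."""
    return np.sign(z) * np.maximum(np.abs(z) - penalty, 0.0)


def subset_positive(matrix: FeatureMatrix, target: str) -> FeatureMatrix:
    """Rows with ``target == 1``; the target column leaves the feature set."""
    if target not in matrix.data.columns:
        raise KeyError(f"target {target!r} not in the feature matrix")
    col = matrix.data[target]
    rows = matrix.data.index[col == 1]
    if len(rows) < 3:
        raise ValueError(
            f"target {target!r} has only {len(rows)} positive subjects (need ≥3)"
        )
    data = matrix.data.loc[rows].drop(columns=[target])
    prov = {c: v for c, v in matrix.provenance.items() if c != target}
    return FeatureMatrix(data=data, provenance=prov)


def _as_frame(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, FeatureMatrix) else matrix


def _neighbor_order(frame: pd.DataFrame) -> np.ndarray:
    """Row-wise neighbor ranking by (Euclidean distance, subject position)."""
    d = squareform(pdist(frame.to_numpy(dtype=float), metric="euclidean"))
    n = len(d)
    order = np.empty((n, n - 1), dtype=int)
    pos = np.arange(n)
    for i in range(n):
        ranked = np.lexsort((pos, d[i]))
        order[i] = ranked[ranked != i]
    return order


def _new_graph(nodes, method: str, parameter, connected: bool | None = None) -> nx.Graph:
    g = nx.Graph(method=method, parameter=parameter)
    if connected is not None:
        g.graph["connected"] = bool(connected)
    g.add_nodes_from(nodes)
    return g


def knn_graph(matrix: FeatureMatrix | pd.DataFrame, k: int) -> nx.Graph:
    """Union-of-neighborhoods kNN graph on the subjects.

    Distance ties are broken by subject order in the matrix, so the
    graph is deterministic.
    """
    frame = _as_frame(matrix)
    n = len(frame)
    if k < 1 or n < k + 1:
        raise ValueError("need k >= 1 and at least k+1 subjects")
    order = _neighbor_order(frame)
    g = _new_graph(frame.index, "knn", int(k))
    ids = list(frame.index)
    for i in range(n):
        for j in order[i, :k]:
            g.add_edge(ids[i], ids[j])
    g.graph["connected"] = nx.is_connected(g)
    return g


def min_k_connected(matrix: FeatureMatrix | pd.DataFrame) -> nx.Graph:
    """The kNN graph at the smallest k whose union graph is connected.

    Minimality is certified on every call: the loop only reaches k after
    observing that k−1 leaves the graph disconnected.  k = n−1 always
    connects (the graph is then complete), so termination is guaranteed
    even with duplicate rows.
    """
    frame = _as_frame(matrix)
    n = len(frame)
    if n < 2:
        raise ValueError("need at least two subjects")
    order = _neighbor_order(frame)
    ids = list(frame.index)
    g = _new_graph(frame.index, "knn", 0)
    for k in range(1, n):
        for i in range(n):
            g.add_edge(ids[i], ids[order[i, k - 1]])
        if nx.is_connected(g):
            g.graph["parameter"] = k
            g.graph["connected"] = True
            return g
    raise AssertionError("unreachable: complete graph is connected")


def subject_correlation(matrix: FeatureMatrix | pd.DataFrame) -> np.ndarray:
    """Pearson correlation between subjects' response vectors.

    A constant response vector (all-0 or all-1) has no defined
    correlation; its entries are set to 0 with a warning, keeping the
    matrix symmetric with a unit diagonal.
    """
    x = _as_frame(matrix).to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two features per subject")
    flat = x.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant subject vector(s): correlation set to 0")
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def ct_graph(
    corr: np.ndarray, threshold: float, node_ids=None
) -> nx.Graph:
    """Edge (i, j) wherever ``corr[i, j] > threshold`` (strict)."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    n = corr.shape[0]
    ids = list(node_ids) if node_ids is not None else list(range(n))
    g = _new_graph(ids, "ct", float(threshold))
    iu, ju = np.triu_indices(n, k=1)
    hit = corr[iu, ju] > threshold
    g.add_edges_from((ids[i], ids[j]) for i, j in zip(iu[hit], ju[hit]))
    g.graph["connected"] = nx.is_connected(g) if n else False
    return g


def _standardize(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    keep = sd > 0
    z = np.zeros_like(data, dtype=float)
    z[:, keep] = (data[:, keep] - mu[keep]) / sd[keep]
    return z, keep


def mb_graph(data: np.ndarray | pd.DataFrame, penalty: float, node_ids=None) -> nx.Graph:
    """Neighborhood-selection graph over the columns of ``data``.

    ``data`` is observations × variables; each variable is lasso-
    regressed (coordinate descent, objective ``(1/2n)‖y − Xw‖² +
    λ‖w‖₁``) on the others after standardization, and the estimated
    neighborhoods are combined with the OR rule.  A penalty at or above
    the largest absolute marginal correlation yields the empty graph.
    Zero-variance variables get empty neighborhoods.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    arr = np.asarray(_as_frame(data) if isinstance(data, (pd.DataFrame, FeatureMatrix)) else data,
                     dtype=float)
    if isinstance(data, pd.DataFrame):
        default_ids = list(data.columns)
    else:
        default_ids = list(range(arr.shape[1]))
    ids = list(node_ids) if node_ids is not None else default_ids
    n_obs, p = arr.shape
    z, active = _standardize(arr)
    g = _new_graph(ids, "mb", float(penalty))

    lasso = Lasso(alpha=penalty, fit_intercept=False, max_iter=10_000, tol=1e-6)
    cols = np.flatnonzero(active)
    for j in cols:
        others = cols[cols != j]
        if len(others) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter
            lasso.fit(z[:, others], z[:, j])
        for w, o in zip(lasso.coef_, others):
            if abs(w) > _EDGE_TOL:
                g.add_edge(ids[j], ids[int(o)])
    g.graph["connected"] = nx.is_connected(g) if p else False
    return g


def glasso_graph(
    data: np.ndarray | pd.DataFrame,
    penalty: float,
    node_ids=None,
    precomputed_corr: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> nx.Graph:
    """Graphical-lasso graph over the columns of ``data``.

    The L1-penalized inverse of the empirical correlation matrix is
    estimated by block coordinate descent (scikit-learn's solver for the
    Friedman–Hastie–Tibshirani formulation); an edge is placed wherever
    an off-diagonal precision entry exceeds the numerical tolerance.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if precomputed_corr is not None:
        corr = np.asarray(precomputed_corr, dtype=float)
        ids = list(node_ids) if node_ids is not None else list(range(len(corr)))
    else:
        arr = np.asarray(
            _as_frame(data) if isinstance(data, (pd.DataFrame, FeatureMatrix)) else data,
            dtype=float,
        )
        z, active = _standardize(arr)
        corr = (z.T @ z) / len(z)
        np.fill_diagonal(corr, 1.0)  # zero-variance columns stay isolated
        if isinstance(data, pd.DataFrame):
            ids = list(node_ids) if node_ids is not None else list(data.columns)
        else:
            ids = list(node_ids) if node_ids is not None else list(range(arr.shape[1]))
    try:
        _, precision = _sk_graphical_lasso(
            corr, alpha=penalty, tol=tol, max_iter=max_iter
        )
    except FloatingPointError as exc:  # non-convergence surfaces as numerics
        raise RuntimeError(
            f"graphical lasso failed to converge at penalty {penalty:g}: {exc}"
        ) from exc
    g = _new_graph(ids, "glasso", float(penalty))
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = np.abs(precision[iu, ju]) > _EDGE_TOL
    g.add_edges_from((ids[i], ids[j]) for i, j in zip(iu[hit], ju[hit]))
    g.graph["connected"] = nx.is_connected(g) if len(ids) else False
    return g


def _node_orientation(
    matrix, method: str
) -> tuple[np.ndarray | None, np.ndarray | None, list]:
    """Resolve input into (obs × subject-variables data, corr, node ids)."""
    if isinstance(matrix, (FeatureMatrix, pd.DataFrame)):
        frame = _as_frame(matrix)
        ids = list(frame.index)
        if method == "ct":
            return None, subject_correlation(frame), ids
        return frame.to_numpy(dtype=float).T, None, ids
    arr = np.asarray(matrix, dtype=float)
    if method == "ct":
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("ct expects a square correlation matrix or a FeatureMatrix")
        return None, arr, list(range(arr.shape[0]))
    return arr, None, list(range(arr.shape[1]))


def sparsest_connected(
    matrix,
    method: Literal["mb", "glasso", "ct"],
    path_size: int = 30,
    min_penalty_ratio: float = 0.01,
    require: Literal["connected", "nonempty"] = "connected",
    glasso_tol: float = 1e-4,
    glasso_max_iter: int = 100,
) -> nx.Graph:
    """Sparsest graph along a monotone parameter path that is connected.

    For CT the path descends through 30 evenly spaced thresholds from
    just below the largest to just below the smallest off-diagonal
    correlation; for MB/glasso it descends a logarithmic penalty path
    from the null-model penalty (the largest absolute off-diagonal
    correlation, above which the estimate is empty).  The scan stops at
    the first connected graph.  If no path point is connected the
    densest one is returned with ``graph.graph["connected"] = False``
    and a warning; ``require="nonempty"`` instead returns the sparsest
    graph with at least one edge.

    When ``matrix`` is a :class:`FeatureMatrix` the nodes are its
    subjects (features act as observations for MB/glasso); a raw array
    is read as observations × variables (or a square correlation matrix
    for CT).
    """
    if method not in ("mb", "glasso", "ct"):
        raise ValueError(f"unknown method {method!r}")
    data, corr, ids = _node_orientation(matrix, method)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two nodes")

    if method == "ct":
        off = corr[np.triu_indices(n, k=1)]
        hi, lo = float(off.max()), float(off.min())
        eps = max(1e-12, 1e-9 * max(abs(hi), 1.0))
        if np.isclose(hi, lo):
            path = [hi - eps]
        else:
            path = list(np.linspace(hi, lo, path_size) - eps)
        build = lambda t: ct_graph(corr, t, ids)  # noqa: E731
    else:
        if data is not None:
            z, _ = _standardize(data)
            base = (z.T @ z) / len(z)
        else:  # pragma: no cover
            base = corr
        lam_max = float(np.abs(base[np.triu_indices(n, k=1)]).max())
        if lam_max <= 0:
            lam_max = 1.0
        path = list(np.geomspace(lam_max, lam_max * min_penalty_ratio, path_size))
        if method == "mb":
            build = lambda lam: mb_graph(data, lam, ids)  # noqa: E731
        else:
            build = lambda lam: glasso_graph(  # noqa: E731
                data, lam, ids, tol=glasso_tol, max_iter=glasso_max_iter
            )

    sparsest_nonempty: nx.Graph | None = None
    last: nx.Graph | None = None
    for param in path:
        try:
            g = build(param)
        except RuntimeError as exc:
            warnings.warn(str(exc))
            continue
        last = g
        if sparsest_nonempty is None and g.number_of_edges() > 0:
            sparsest_nonempty = g
        if require == "nonempty" and g.number_of_edges() > 0:
            return g
        if require == "connected" and g.graph.get("connected"):
            return g
    if require == "nonempty" and sparsest_nonempty is not None:
        return sparsest_nonempty
    if last is None:
        raise RuntimeError(f"every {method} path point failed")
    warnings.warn(
        f"no connected {method} graph on the {len(path)}-point path; "
        "returning the densest scanned graph"
    )
    return last


def infer_graph(
    matrix: FeatureMatrix | pd.DataFrame,
    method: InferenceMethod,
    path_size: int = 30,
    **kwargs,
) -> nx.Graph:
    """Infer a subject graph with one of the four methods at minimal density."""
    if method == "knn":
        return min_k_connected(matrix)
    return sparsest_connected(matrix, method, path_size=path_size, **kwargs)


def write_graph(graph: nx.Graph, path, edge_list_path=None) -> None:
    """GraphML export (plus an optional 2-column TSV edge list)."""
    g = graph.copy()
    for v in g.nodes:
        g.nodes[v]["subject_id"] = str(v)
    nx.write_graphml(g, path)
    if edge_list_path is not None:
        with open(edge_list_path, "w") as fh:
            for u, v in sorted(map(sorted, g.edges)):
                fh.write(f"{u}\t{v}\n")


def read_graph(path) -> nx.Graph:
    return nx.read_graphml(path)
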