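"""Step-forward wrapper feature selection scored by ROC AUC.

A greedy wrapper around an L2-stabilized logistic regression: starting
from the empty set, repeatedly add the candidate feature whose refit
classifier attains the highest AUC on a held-out stratified split, until
the requested set size is reached.  Selections for nested sizes share
one greedy run, so the size-15 set is a prefix of the size-20 set under
the same split.  The "all features" set is the full post-curation pool
and is returned without search.

The holdout is a stratified 70/30 train/test split with a fixed seed.
Candidate ties on holdout AUC are broken toward the lexicographically
smallest feature name; together with the deterministic convex fit this
makes selection a pure function of (data, sizes, split seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .preprocess import FeatureMatrix

__all__ = ["FeatureSet", "auc", "fit_linear_classifier", "step_forward_select",
           "write_feature_set", "read_feature_set"]


@dataclass(frozen=True)
class FeatureSet:
    """An ordered greedy selection with its holdout-AUC audit trail."""

    target_name: str
    size: int
    ordered_features: tuple[str, ...]
    auc_trajectory: tuple[float, ...]
    split_seed: int

    def __post_init__(self) -> None:
        if len(self.ordered_features) != self.size:
            raise ValueError("ordered_features length must equal size")
        if len(set(self.ordered_features)) != self.size:
            raise ValueError("selected features must be unique")
        if len(self.auc_trajectory) != self.size:
            raise ValueError("auc_trajectory must have one entry per feature")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUC: P(random positive outscores random negative), ties ½."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined when only one class is present")
    return float(roc_auc_score(labels, scores))


def fit_linear_classifier(
    x: np.ndarray | pd.DataFrame, y: np.ndarray, ridge_c: float = 100.0
) -> LogisticRegression:
    """Deterministic logistic fit with a weak ridge penalty.

    The penalty (``C=100``, i.e. light L2) guarantees a finite optimum
    even under complete separation, which binary survey features produce
    routinely.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D design with at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training rows")
    model = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=1000, tol=1e-8)
    model.fit(x, y)
    return model


def _holdout(y: np.ndarray, test_size: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=y
    )
    for part in (train, test):
        if len(np.unique(y[part])) < 2:
            raise ValueError("split left a single class in train or test")
    return train, test


def step_forward_select(
    matrix: FeatureMatrix | pd.DataFrame,
    y: Sequence[int],
    target_name: str,
    sizes: Sequence[int | str],
    split_seed: int = 0,
    test_size: float = 0.3,
) -> list[FeatureSet]:
    """Greedy step-forward selection for each requested size.

    ``sizes`` may mix integers and the string ``"all"`` (the full
    feature pool, no search).  Sizes above the pool size are rejected.
    """
    frame = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(y)
    if len(y) != len(frame):
        raise ValueError("target length must match the number of subjects")
    pool = list(frame.columns)
    requested: list[int] = []
    want_all = False
    for s in sizes:
        if s == "all":
            want_all = True
        else:
            s = int(s)
            if not 1 <= s <= len(pool):
                raise ValueError(f"size {s} exceeds the {len(pool)}-feature pool")
            requested.append(s)

    train, test = _holdout(y, test_size, split_seed)
    x_all = frame.to_numpy(dtype=float)
    max_size = max(requested, default=0)

    selected: list[str] = []
    trajectory: list[float] = []
    remaining = sorted(pool)
    for _ in range(max_size):
        best_name, best_auc = None, -np.inf
        for name in remaining:  # lexicographic order ⇒ deterministic ties
            cols = [frame.columns.get_loc(c) for c in selected + [name]]
            model = fit_linear_classifier(x_all[np.ix_(train, cols)], y[train])
            scores = model.decision_function(x_all[np.ix_(test, cols)])
            a = auc(scores, y[test])
            if a > best_auc:
                best_name, best_auc = name, a
        assert best_name is not None
        selected.append(best_name)
        remaining.remove(best_name)
        trajectory.append(best_auc)

    out = []
    for s in sorted(requested):
        out.append(
            FeatureSet(target_name, s, tuple(selected[:s]), tuple(trajectory[:s]),
                       split_seed)
        )
    if want_all:
        traj = _prefix_trajectory(frame, y, train, test)
        out.append(FeatureSet(target_name, len(pool), tuple(pool), traj, split_seed))
    return out


def _prefix_trajectory(
    frame: pd.DataFrame, y: np.ndarray, train: np.ndarray, test: np.ndarray
) -> tuple[float, ...]:
    """Holdout AUC of nested column-order prefixes (audit for the full set)."""
    x = frame.to_numpy(dtype=float)
    traj = []
    for j in range(1, x.shape[1] + 1):
        model = fit_linear_classifier(x[np.ix_(train, range(j))], y[train])
        traj.append(auc(model.decision_function(x[np.ix_(test, range(j))]), y[test]))
    return tuple(traj)


def write_feature_set(fs: FeatureSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "target": fs.target_name,
                "size": fs.size,
                "ordered_features": list(fs.ordered_features),
                "auc_trajectory": list(fs.auc_trajectory),
                "split_seed": fs.split_seed,
            },
            indent=2,
        )
    )


def read_feature_set(path: str | Path) -> FeatureSet:
    doc = json.loads(Path(path).read_text())
    return FeatureSet(
        doc["target"],
        doc["size"],
        tuple(doc["ordered_features"]),
        tuple(doc["auc_trajectory"]),
        doc["split_seed"],
    )
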