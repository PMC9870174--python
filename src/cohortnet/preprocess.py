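"""Curation of a raw survey table into a complete binary feature matrix.

The pipeline is: drop questions with too much nonresponse, one-hot
expand multi-level questions, collapse every remaining token that is not
an explicit "yes" to 0 ("skipped" answers are read as no), and prune one
member of every highly correlated feature pair.  The result is a
rectangular 0/1 matrix with no missing entries, the substrate for
feature selection and graph inference.

Pearson correlation on 0/1 columns is the phi coefficient; the filter
compares ``|r|`` to the threshold.  When a pair exceeds it, the member
with the higher mean absolute correlation to all other features is
discarded (ties fall back to lexicographic name order), which removes
the more redundant of the two deterministically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import MISSING, SKIPPED, YES, SurveyTable

__all__ = [
    "FeatureMatrix",
    "drop_sparse_features",
    "one_hot_encode",
    "skipped_to_no",
    "correlation_filter",
    "curate",
    "write_curation_report",
]

_BINARY_TOKENS = {YES, "no", SKIPPED, MISSING}


@dataclass
class FeatureMatrix:
    """A complete subjects × features 0/1 matrix.

    ``provenance`` maps each derived one-hot column back to its source
    question and level; pass-through binary questions map to themselves.
    """

    data: pd.DataFrame
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise ValueError("feature names must be unique")
        if self.data.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("feature matrix must contain only 0/1 values")
        self.data = self.data.astype(np.int8)

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)


def _missing_mask(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.isna() | (frame == MISSING)


def drop_sparse_features(
    table: SurveyTable, min_complete_fraction: float = 0.6, keep: Iterable[str] = ()
) -> SurveyTable:
    """Retain features whose non-missing fraction meets the threshold.

    ``keep`` columns (e.g. target variables) are exempt from the rule.
    """
    if not 0 < min_complete_fraction <= 1:
        raise ValueError("min_complete_fraction must lie in (0, 1]")
    complete = 1.0 - _missing_mask(table.data).mean(axis=0)
    keep = set(keep)
    cols = [
        c
        for c in table.data.columns
        if c in keep or complete[c] >= min_complete_fraction
    ]
    if not cols:
        raise ValueError("every feature fell below the completeness threshold")
    return SurveyTable(data=table.data[cols], ground_truth=table.ground_truth)


def _is_binary(col: pd.Series) -> bool:
    return set(col.dropna().unique()) <= _BINARY_TOKENS


def one_hot_encode(table: SurveyTable) -> tuple[SurveyTable, dict[str, tuple[str, str]]]:
    """Expand multi-level questions into one yes/no column per level.

    Binary yes/no questions pass through unchanged.  A missing (or
    skipped) source value propagates as missing to every derived column,
    so exactly one derived column per question is "yes" whenever the
    source was observed.  Single-level columns pass through as constants
    with a warning.
    """
    columns: dict[str, pd.Series] = {}
    provenance: dict[str, tuple[str, str]] = {}
    for name in table.data.columns:
        col = table.data[name]
        if _is_binary(col):
            columns[name] = col
            provenance[name] = (name, YES)
            continue
        observed = sorted(
            v for v in col.dropna().unique() if v not in (MISSING, SKIPPED)
        )
        if len(observed) < 2:
            warnings.warn(f"column {name!r} has a single observed level; passed through")
        for level in observed:
            derived = f"{name}={level}"
            hidden = col.isna() | (col == MISSING) | (col == SKIPPED)
            vals = np.where(col == level, YES, "no").astype(object)
            vals[hidden.to_numpy()] = MISSING
            columns[derived] = pd.Series(vals, index=col.index)
            provenance[derived] = (name, level)
    out = SurveyTable(
        data=pd.DataFrame(columns, index=table.data.index),
        ground_truth=table.ground_truth,
    )
    return out, provenance


def skipped_to_no(table: SurveyTable) -> SurveyTable:
    """Map "yes" to 1 and every other token (no/skipped/missing) to 0."""
    data = (table.data == YES).astype(np.int8)
    return SurveyTable(data=data, ground_truth=table.ground_truth)


def correlation_filter(
    matrix: FeatureMatrix,
    threshold: float = 0.8,
    protected: Iterable[str] = (),
    log: list | None = None,
) -> FeatureMatrix:
    """Drop features until no retained pair has ``|r|`` above the threshold.

    Zero-variance features carry no correlation signal; they are
    excluded from the computation and retained with a warning.
    ``protected`` columns are never dropped (their partner goes
    instead).  Each drop is appended to ``log`` as
    ``{"dropped", "partner", "r"}``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if matrix.data.shape[1] < 2:
        raise ValueError("need at least two features")
    protected = set(protected)

    variances = matrix.data.var(axis=0)
    constant = [c for c in matrix.data.columns if variances[c] == 0]
    if constant:
        warnings.warn(
            f"{len(constant)} zero-variance feature(s) retained without "
            f"correlation screening: {constant[:5]}..."
        )
    active = [c for c in matrix.data.columns if variances[c] > 0]
    corr = matrix.data[active].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)

    alive = list(range(len(active)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        a, b = active[alive[i]], active[alive[j]]
        mean_abs = sub.mean(axis=0) * len(alive) / max(len(alive) - 1, 1)
        if a in protected and b in protected:
            warnings.warn(f"correlated pair {a!r}/{b!r} both protected; kept")
            corr[alive[i], alive[j]] = 0.0
            corr[alive[j], alive[i]] = 0.0
            continue
        if a in protected:
            victim_pos, partner = j, a
        elif b in protected:
            victim_pos, partner = i, b
        else:
            # drop the more redundant member; ties by name
            key_i = (mean_abs[i], a)
            key_j = (mean_abs[j], b)
            victim_pos, partner = (i, b) if key_i >= key_j else (j, a)
        victim = active[alive[victim_pos]]
        if log is not None:
            log.append(
                {"dropped": victim, "partner": partner, "r": float(sub[i, j])}
            )
        del alive[victim_pos]
        if len(alive) < 2:
            break

    kept = set(active[p] for p in alive) | set(constant)
    cols = [c for c in matrix.data.columns if c in kept]
    prov = {c: matrix.provenance.get(c, (c, YES)) for c in cols}
    return FeatureMatrix(data=matrix.data[cols], provenance=prov)


def curate(
    table: SurveyTable,
    min_complete_fraction: float = 0.6,
    corr_threshold: float = 0.8,
    exclude: Sequence[str] = (),
    protected: Sequence[str] = (),
) -> tuple[FeatureMatrix, dict]:
    """Full curation: drop sparse → one-hot → tokens to 0/1 → correlation filter.

    ``exclude`` removes metadata-like columns (ids, site codes) up
    front; ``protected`` columns (targets) bypass both the sparsity and
    the correlation drop.  Returns the matrix and a machine-readable
    report of everything that was removed and why.
    """
    report: dict = {"excluded": list(exclude), "dropped_sparse": {}, "dropped_correlated": []}
    data = table.data.drop(columns=list(exclude), errors="ignore")
    table = SurveyTable(data=data, ground_truth=table.ground_truth)

    complete = 1.0 - _missing_mask(table.data).mean(axis=0)
    kept = drop_sparse_features(table, min_complete_fraction, keep=protected)
    report["dropped_sparse"] = {
        c: round(1.0 - float(complete[c]), 4)
        for c in table.data.columns
        if c not in kept.data.columns
    }

    encoded, provenance = one_hot_encode(kept)
    report["one_hot"] = {
        derived: {"source": src, "level": lvl}
        for derived, (src, lvl) in provenance.items()
        if derived != src
    }

    binary = skipped_to_no(encoded)
    matrix = FeatureMatrix(data=binary.data, provenance=provenance)

    corr_log: list = []
    matrix = correlation_filter(matrix, corr_threshold, protected=protected, log=corr_log)
    report["dropped_correlated"] = corr_log
    report["n_features"] = matrix.data.shape[1]
    report["n_subjects"] = matrix.data.shape[0]
    return matrix, report


def write_curation_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
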