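"""Ground-truth generators: survey tables, planted graphs, Gaussian data.

Three generators give every downstream stage a known answer to recover:

``generate_survey``
    A subjects × questions table shaped like a large respondent-driven
    health survey: yes/no questions, multi-level categorical questions,
    heavy nonresponse concentrated in a subset of questions, binary
    target variables (e.g. HIV status, recent homelessness), and latent
    subject subgroups with subgroup-specific response profiles.
    Missingness is missing-completely-at-random per cell; a small
    "skipped" rate emulates respondents declining individual questions.

``generate_planted_graph``
    A planted-partition (stochastic block) graph: within-block edge
    probability ``p_in``, between-block ``p_out``, returned together
    with the planted partition.

``generate_gaussian_precision``
    Zero-mean multivariate normal samples whose precision (inverse
    covariance) matrix has a known sparse support — the ground truth for
    conditional-independence graph estimators.

All three are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from .cluster import Partition

__all__ = [
    "TargetSpec",
    "MultiValuedSpec",
    "SurveyConfig",
    "SurveyTable",
    "generate_survey",
    "generate_planted_graph",
    "generate_gaussian_precision",
    "chain_precision",
    "default_survey_config",
    "write_survey_csv",
    "read_survey_csv",
    "write_labels_csv",
    "save_config",
    "load_config",
]

MISSING = ""
SKIPPED = "skipped"
YES = "yes"
NO = "no"


@dataclass(frozen=True)
class TargetSpec:
    """A binary target variable with one positive probability per cluster."""

    name: str
    cluster_positive_prob: tuple[float, ...]


@dataclass(frozen=True)
class MultiValuedSpec:
    """A categorical question: named levels and per-cluster level weights."""

    name: str
    levels: tuple[str, ...]
    cluster_level_prob: tuple[tuple[float, ...], ...]  # (n_clusters, n_levels)


@dataclass
class SurveyConfig:
    """Full specification of a synthetic survey draw.

    ``binary_profiles[k, j]`` is the probability that a member of
    planted cluster ``k`` answers yes to binary question ``j``.  The
    seed fully determines the generated table.
    """

    n_subjects: int
    cluster_sizes: tuple[int, ...]
    binary_features: tuple[str, ...]
    binary_profiles: np.ndarray
    multivalued: tuple[MultiValuedSpec, ...]
    missing_rates: dict[str, float]
    targets: tuple[TargetSpec, ...]
    seed: int
    skipped_rate: float = 0.02

    def __post_init__(self) -> None:
        self.binary_profiles = np.asarray(self.binary_profiles, dtype=float)
        k = len(self.cluster_sizes)
        if self.n_subjects <= 0 or k == 0:
            raise ValueError("need a positive subject count and at least one cluster")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("every planted cluster must be nonempty")
        if sum(self.cluster_sizes) != self.n_subjects:
            raise ValueError("cluster sizes must sum to n_subjects")
        if self.binary_profiles.shape != (k, len(self.binary_features)):
            raise ValueError("binary_profiles must be (n_clusters, n_binary_features)")
        if not ((self.binary_profiles >= 0) & (self.binary_profiles <= 1)).all():
            raise ValueError("profile probabilities must lie in [0, 1]")
        for spec in self.multivalued:
            arr = np.asarray(spec.cluster_level_prob, dtype=float)
            if arr.shape != (k, len(spec.levels)):
                raise ValueError(f"{spec.name}: level probabilities must be (K, L)")
            if (arr < 0).any() or not np.allclose(arr.sum(axis=1), 1.0):
                raise ValueError(f"{spec.name}: level probabilities must sum to 1")
        for name, rate in self.missing_rates.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missing rate for {name} must be in [0, 1)")
        for t in self.targets:
            if len(t.cluster_positive_prob) != k:
                raise ValueError(f"target {t.name}: need one probability per cluster")
            if any(not 0 <= p <= 1 for p in t.cluster_positive_prob):
                raise ValueError(f"target {t.name}: probabilities must lie in [0, 1]")
        if not 0 <= self.skipped_rate < 1:
            raise ValueError("skipped_rate must be in [0, 1)")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def feature_names(self) -> list[str]:
        return list(self.binary_features) + [m.name for m in self.multivalued]

    @property
    def target_names(self) -> list[str]:
        return [t.name for t in self.targets]


@dataclass
class SurveyTable:
    """A raw subjects × features table of string-valued responses.

    Binary questions use the tokens ``yes``/``no``/``skipped``/``""``
    (empty string = missing); categorical questions use their level
    names.  ``ground_truth`` carries the planted cluster of each subject
    when the table came from the generator.
    """

    data: pd.DataFrame
    ground_truth: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        if self.ground_truth is not None and not self.ground_truth.index.equals(
            self.data.index
        ):
            raise ValueError("ground-truth labels must cover exactly the subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.data)


def _subject_ids(n: int) -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"S{i:0{width}d}" for i in range(n)], name="subject_id")


def generate_survey(config: SurveyConfig) -> SurveyTable:
    """Draw a survey table with planted cluster structure (see module docs)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    labels = np.repeat(np.arange(config.n_clusters), config.cluster_sizes)
    ids = _subject_ids(n)

    columns: dict[str, np.ndarray] = {}
    for j, name in enumerate(config.binary_features):
        p = config.binary_profiles[labels, j]
        vals = np.where(rng.random(n) < p, YES, NO).astype(object)
        skip = rng.random(n) < config.skipped_rate
        vals[skip] = SKIPPED
        miss = rng.random(n) < config.missing_rates.get(name, 0.0)
        vals[miss] = MISSING
        columns[name] = vals

    for spec in config.multivalued:
        probs = np.asarray(spec.cluster_level_prob, dtype=float)
        cum = probs[labels].cumsum(axis=1)
        draws = (rng.random(n)[:, None] < cum).argmax(axis=1)
        vals = np.asarray(spec.levels, dtype=object)[draws]
        miss = rng.random(n) < config.missing_rates.get(spec.name, 0.0)
        vals[miss] = MISSING
        columns[spec.name] = vals

    for t in config.targets:  # targets are complete: no skips, no missingness
        p = np.asarray(t.cluster_positive_prob)[labels]
        columns[t.name] = np.where(rng.random(n) < p, YES, NO).astype(object)

    frame = pd.DataFrame(columns, index=ids, dtype=object)
    truth = pd.Series(labels, index=ids, name="cluster")
    return SurveyTable(data=frame, ground_truth=truth)


def generate_planted_graph(
    n_nodes: int, n_clusters: int, p_in: float, p_out: float, seed: int
) -> tuple[nx.Graph, Partition]:
    """Planted-partition graph with near-equal blocks plus its ground truth."""
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    if n_clusters <= 0 or n_nodes < n_clusters:
        raise ValueError("need at least one node per cluster")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_nodes, n_clusters)
    sizes = [base + (1 if k < extra else 0) for k in range(n_clusters)]
    labels = np.repeat(np.arange(n_clusters), sizes)

    iu, ju = np.triu_indices(n_nodes, k=1)
    p = np.where(labels[iu] == labels[ju], p_in, p_out)
    keep = rng.random(len(p)) < p
    graph = nx.Graph()
    graph.add_nodes_from(range(n_nodes))
    graph.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    part = Partition(labels={i: int(labels[i]) for i in range(n_nodes)}, method="planted")
    return graph, part


def chain_precision(n_variables: int, coupling: float = 0.45) -> np.ndarray:
    """Tridiagonal precision matrix of a first-order Gaussian chain.

    Unit diagonal with ``coupling`` on the first off-diagonals; positive
    definite for any length when ``|coupling| < 1/2``.
    """
    p = np.eye(n_variables)
    idx = np.arange(n_variables - 1)
    p[idx, idx + 1] = p[idx + 1, idx] = coupling
    return p


def generate_gaussian_precision(
    n_samples: int,
    n_variables: int,
    structure: str = "chain",
    seed: int = 0,
) -> tuple[np.ndarray, frozenset[tuple[int, int]]]:
    """Multivariate-normal samples with a known sparse precision support.

    Returns ``(X, edges)`` where ``X`` is ``n_samples × n_variables``
    and ``edges`` is the set of (i < j) pairs with a nonzero
    off-diagonal precision entry.  ``structure='chain'`` uses
    :func:`chain_precision`; ``structure='random'`` places ±0.3
    couplings on a sparse random support and jitters the diagonal until
    positive definite.
    """
    if n_variables < 2:
        raise ValueError("need at least two variables")
    rng = np.random.default_rng(seed)
    if structure == "chain":
        prec = chain_precision(n_variables)
    elif structure == "random":
        prec = np.eye(n_variables)
        iu, ju = np.triu_indices(n_variables, k=1)
        support = rng.random(len(iu)) < min(1.0, 2.0 / n_variables)
        signs = rng.choice([-0.3, 0.3], size=len(iu))
        prec[iu[support], ju[support]] = signs[support]
        prec[ju[support], iu[support]] = signs[support]
        for _ in range(50):  # jitter the diagonal until positive definite
            eigmin = np.linalg.eigvalsh(prec).min()
            if eigmin > 1e-6:
                break
            prec[np.diag_indices(n_variables)] += abs(eigmin) + 0.1
        else:  # pragma: no cover - cannot trigger with bounded couplings
            raise RuntimeError("failed to make the precision positive definite")
    else:
        raise ValueError(f"unknown structure {structure!r}")

    cov = np.linalg.inv(prec)
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((n_samples, n_variables)) @ chol.T
    off = np.abs(prec) > 1e-12
    iu, ju = np.triu_indices(n_variables, k=1)
    edges = frozenset(
        (int(i), int(j)) for i, j in zip(iu, ju) if off[i, j]
    )
    return x, edges


# ---------------------------------------------------------------------------
# default study conditions


def default_survey_config(seed: int = 0, n_subjects: int = 800) -> SurveyConfig:
    """The package's reference synthetic-survey conditions.

    800 subjects in four equal latent clusters; 72 raw questions: 36
    well-answered yes/no questions whose per-cluster yes-probabilities
    are drawn from {0.85, 0.15} (the planted signal), 12 multi-level
    categorical questions with a cluster-preferred level, and 24 poorly
    answered yes/no questions missing 50–95% of their values (these
    emulate the bulk of low-participation questions in real RDS surveys
    and are pruned during curation).  Four binary targets with
    cluster-dependent positive rates span roughly 10–45% prevalence,
    matching the relative positive-set sizes of typical targets such as
    HIV status (rare) versus recent homelessness (common).

    The configuration, including every random profile, is a
    deterministic function of ``seed``.
    """
    if n_subjects < 8:
        raise ValueError("default config needs at least 8 subjects")
    rng = np.random.default_rng(seed)
    k = 4
    base, extra = divmod(n_subjects, k)
    sizes = tuple(base + (1 if i < extra else 0) for i in range(k))

    signal = tuple(f"q{j:02d}" for j in range(1, 37))
    profiles = rng.choice([0.85, 0.15], size=(k, len(signal)))

    multis = []
    for j in range(1, 13):
        levels = tuple(f"level{l}" for l in range(3))
        pref = rng.integers(0, 3, size=k)
        arr = np.full((k, 3), 0.15)
        arr[np.arange(k), pref] = 0.70
        multis.append(
            MultiValuedSpec(f"m{j:02d}", levels, tuple(map(tuple, arr)))
        )

    noise = tuple(f"x{j:02d}" for j in range(1, 25))
    noise_profiles = np.full((k, len(noise)), 0.5)

    missing = {name: float(r) for name, r in zip(signal, rng.uniform(0.0, 0.2, len(signal)))}
    missing.update(
        {m.name: float(r) for m, r in zip(multis, rng.uniform(0.0, 0.2, len(multis)))}
    )
    missing.update(
        {name: float(r) for name, r in zip(noise, rng.uniform(0.5, 0.95, len(noise)))}
    )

    targets = (
        TargetSpec("hiv", (0.35, 0.05, 0.04, 0.04)),
        TargetSpec("idu", (0.60, 0.50, 0.08, 0.08)),
        TargetSpec("homeless", (0.70, 0.15, 0.65, 0.20)),
        TargetSpec("insurance", (0.15, 0.70, 0.20, 0.55)),
    )

    return SurveyConfig(
        n_subjects=n_subjects,
        cluster_sizes=sizes,
        binary_features=signal + noise,
        binary_profiles=np.hstack([profiles, noise_profiles]),
        multivalued=tuple(multis),
        missing_rates=missing,
        targets=targets,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk formats


def write_survey_csv(table: SurveyTable, path: str | Path) -> None:
    """One row per subject, header of feature names, "" for missing."""
    table.data.to_csv(path)


def write_labels_csv(table: SurveyTable, path: str | Path) -> None:
    if table.ground_truth is None:
        raise ValueError("table has no ground-truth labels")
    table.ground_truth.to_csv(path)


def read_survey_csv(path: str | Path, labels_path: str | Path | None = None) -> SurveyTable:
    frame = pd.read_csv(path, index_col=0, dtype=object, keep_default_na=False)
    truth = None
    if labels_path is not None:
        truth = pd.read_csv(labels_path, index_col=0)["cluster"]
    return SurveyTable(data=frame, ground_truth=truth)


def save_config(config: SurveyConfig, path: str | Path) -> None:
    """Serialize a survey configuration as a YAML key-value document."""
    doc = {
        "n_subjects": config.n_subjects,
        "cluster_sizes": list(config.cluster_sizes),
        "binary_features": list(config.binary_features),
        "binary_profiles": config.binary_profiles.tolist(),
        "multivalued": [
            {
                "name": m.name,
                "levels": list(m.levels),
                "cluster_level_prob": [list(row) for row in m.cluster_level_prob],
            }
            for m in config.multivalued
        ],
        "missing_rates": dict(config.missing_rates),
        "targets": [
            {"name": t.name, "cluster_positive_prob": list(t.cluster_positive_prob)}
            for t in config.targets
        ],
        "skipped_rate": config.skipped_rate,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> SurveyConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return SurveyConfig(
        n_subjects=doc["n_subjects"],
        cluster_sizes=tuple(doc["cluster_sizes"]),
        binary_features=tuple(doc["binary_features"]),
        binary_profiles=np.asarray(doc["binary_profiles"], dtype=float),
        multivalued=tuple(
            MultiValuedSpec(
                m["name"],
                tuple(m["levels"]),
                tuple(tuple(row) for row in m["cluster_level_prob"]),
            )
            for m in doc.get("multivalued", [])
        ),
        missing_rates={k: float(v) for k, v in doc.get("missing_rates", {}).items()},
        targets=tuple(
            TargetSpec(t["name"], tuple(t["cluster_positive_prob"]))
            for t in doc.get("targets", [])
        ),
        seed=doc["seed"],
        skipped_rate=doc.get("skipped_rate", 0.02),
    )
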