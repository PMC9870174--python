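"""End-to-end survey-mining pipeline.

For each binary target variable: curate the raw table into a complete
0/1 matrix, select feature sets of size 15, 20 and "all" by step-forward
AUC search, restrict to the target-positive subjects, infer subject
graphs with kNN / MB / glasso / CT at minimal edge density, cluster each
graph with Louvain, Leiden and NBR-Clust (VAT and integrity), score
every clustering with the five internal validity indices, rank the whole
candidate pool with the points scheme, and profile the winning
clustering's composition with small-cluster suppression.

A stage failure (e.g. a target with almost no positive subjects, or a
graph too degenerate to cluster) aborts that combination only and is
recorded in the per-target error list.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import Partition, leiden, louvain, nbr_clust_both
from .feature_select import FeatureSet, step_forward_select, write_feature_set
from .graph_infer import infer_graph, subset_positive
from .preprocess import FeatureMatrix, curate, write_curation_report
from .report import ClusterProfile, export_annotated_graph, profile_clusters, profiles_to_frame
from .synthetic import SurveyConfig, SurveyTable
from .validity import DegenerateClusteringError, RankResult, ScoreCard, rank, score_partition

__all__ = [
    "PipelineConfig",
    "TargetResult",
    "PipelineResult",
    "run_pipeline",
    "expected_feature_majority",
    "planted_profile_agreement",
]

INFERENCE_METHODS = ("knn", "mb", "glasso", "ct")
CLUSTERERS = ("louvain", "leiden", "nbr_vat", "nbr_integrity")


@dataclass
class PipelineConfig:
    """Tunable pipeline settings (defaults are the reference conditions)."""

    sizes: tuple = (15, 20, "all")
    min_complete_fraction: float = 0.6
    corr_threshold: float = 0.8
    test_size: float = 0.3
    path_size: int = 12          # parameter-path resolution for MB/glasso/CT
    min_cluster_size: int = 10   # profile suppression threshold
    exclude: tuple[str, ...] = ()
    inference_methods: tuple[str, ...] = INFERENCE_METHODS
    clusterers: tuple[str, ...] = CLUSTERERS


@dataclass
class TargetResult:
    target: str
    seed: int
    n_positive: int = 0
    feature_sets: list[FeatureSet] = field(default_factory=list)
    graphs: dict = field(default_factory=dict)        # (method, size) -> nx.Graph
    partitions: dict = field(default_factory=dict)    # (method, clusterer, size) -> Partition
    scorecards: list[ScoreCard] = field(default_factory=list)
    rank_result: RankResult | None = None
    winner: tuple | None = None
    winner_partition: Partition | None = None
    profiles: list[ClusterProfile] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    curation_report: dict
    targets: dict[str, TargetResult]
    seed: int
    elapsed_seconds: float


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _size_label(size) -> str:
    return "all" if size == "all" else str(size)


def _run_target(
    matrix: FeatureMatrix,
    target: str,
    cfg: PipelineConfig,
    seed: int,
) -> TargetResult:
    res = TargetResult(target=target, seed=seed)
    y = matrix.data[target].to_numpy()
    pool = matrix.data.drop(columns=[target])

    sizes = [s for s in cfg.sizes]
    res.feature_sets = step_forward_select(
        pool, y, target, sizes, split_seed=seed, test_size=cfg.test_size
    )

    positives = subset_positive(matrix, target)
    res.n_positive = len(positives.data)

    for fs in res.feature_sets:
        label = _size_label("all" if fs.size == len(pool.columns) else fs.size)
        sub = positives.data[list(fs.ordered_features)]
        for method in cfg.inference_methods:
            try:
                graph = infer_graph(sub, method, path_size=cfg.path_size)
            except Exception as exc:  # record and move on
                res.errors.append(f"{method}/{label}: inference failed: {exc}")
                continue
            res.graphs[(method, label)] = graph
            _cluster_graph(res, graph, sub, method, label, cfg, seed)

    if len(res.scorecards) < 2:
        res.errors.append("fewer than two scoreable clusterings; no ranking")
        return res
    res.rank_result = rank(res.scorecards)
    res.winner = res.rank_result.winner
    res.winner_partition = res.partitions[res.winner]
    res.profiles = profile_clusters(
        positives.data, res.winner_partition, cfg.min_cluster_size
    )
    return res


def _cluster_graph(
    res: TargetResult,
    graph: nx.Graph,
    sub: pd.DataFrame,
    method: str,
    label: str,
    cfg: PipelineConfig,
    seed: int,
) -> None:
    if graph.number_of_edges() == 0:
        res.errors.append(f"{method}/{label}: empty graph, not clustered")
        return
    parts: dict[str, Partition] = {}
    if "louvain" in cfg.clusterers:
        parts["louvain"] = louvain(graph, seed=seed)
    if "leiden" in cfg.clusterers:
        parts["leiden"] = leiden(graph, seed=seed)
    if {"nbr_vat", "nbr_integrity"} & set(cfg.clusterers):
        both = nbr_clust_both(graph, seed=seed)
        if "nbr_vat" in cfg.clusterers:
            parts["nbr_vat"] = both["vat"]
        if "nbr_integrity" in cfg.clusterers:
            parts["nbr_integrity"] = both["integrity"]
    x = sub.to_numpy(dtype=float)
    order = list(sub.index)
    for clusterer, part in parts.items():
        cid = (method, clusterer, label)
        res.partitions[cid] = part
        labels = np.array([part.labels[v] for v in order])
        try:
            res.scorecards.append(score_partition(x, labels, cid))
        except DegenerateClusteringError as exc:
            res.errors.append(f"{method}/{clusterer}/{label}: unscoreable: {exc}")


def run_pipeline(
    table: SurveyTable,
    targets: Sequence[str],
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full per-target pipeline; see module docstring."""
    cfg = config or PipelineConfig()
    t0 = time.time()
    matrix, report = curate(
        table,
        min_complete_fraction=cfg.min_complete_fraction,
        corr_threshold=cfg.corr_threshold,
        exclude=cfg.exclude,
        protected=tuple(targets),
    )
    missing = [t for t in targets if t not in matrix.data.columns]
    if missing:
        raise KeyError(f"targets not present after curation: {missing}")

    results: dict[str, TargetResult] = {}
    for target, child in zip(targets, _child_seeds(seed, len(targets))):
        try:
            results[target] = _run_target(matrix, target, cfg, child)
        except Exception as exc:
            res = TargetResult(target=target, seed=child)
            res.errors.append(f"target aborted: {exc}")
            results[target] = res

    out = PipelineResult(
        matrix=matrix,
        curation_report=report,
        targets=results,
        seed=seed,
        elapsed_seconds=time.time() - t0,
    )
    if out_dir is not None:
        _write_artifacts(out, Path(out_dir), cfg)
    return out


def _write_artifacts(result: PipelineResult, out_dir: Path, cfg: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_curation_report(result.curation_report, out_dir / "curation_report.json")
    for target, res in result.targets.items():
        tdir = out_dir / target
        tdir.mkdir(exist_ok=True)
        for fs in res.feature_sets:
            write_feature_set(fs, tdir / f"features_{fs.size}.json")
        for (method, label), graph in res.graphs.items():
            part = None
            for clusterer in cfg.clusterers:
                part = res.partitions.get((method, clusterer, label))
                if part is not None:
                    break
            if part is not None:
                export_annotated_graph(graph, part, tdir / f"graph_{method}_{label}.graphml")
        for (method, clusterer, label), part in res.partitions.items():
            frame = pd.DataFrame(
                sorted(part.labels.items()), columns=["subject_id", "cluster"]
            )
            frame.to_csv(tdir / f"partition_{method}_{clusterer}_{label}.csv", index=False)
        if res.scorecards:
            rows = [
                {"method": cid[0], "clusterer": cid[1], "n_features": cid[2],
                 **sc.as_dict()}
                for sc in res.scorecards
                for cid in [sc.clustering_id]
            ]
            pd.DataFrame(rows).to_csv(tdir / "scores.csv", index=False)
        if res.rank_result is not None:
            doc = {
                "winner": list(res.rank_result.winner),
                "points": {"/".join(map(str, k)): v
                           for k, v in res.rank_result.points.items()},
                "tiebreak_log": _jsonable(res.rank_result.tiebreak_log),
                "withheld": _jsonable(res.rank_result.withheld),
                "errors": res.errors,
                "seed": res.seed,
            }
            (tdir / "rank.json").write_text(json.dumps(doc, indent=2))
        visible = profiles_to_frame(res.profiles)
        if len(visible):
            visible.to_csv(tdir / "profile.csv")
        sizes = {str(p.cluster): p.size for p in res.profiles}
        (tdir / "cluster_sizes.json").write_text(json.dumps(sizes, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# ground-truth evaluation of a pipeline run (synthetic data only)


def expected_feature_majority(config: SurveyConfig, feature_names: Sequence[str]) -> pd.DataFrame:
    """Planted majority answer (True = yes) per cluster for curated columns.

    Columns that cannot be traced to a generator feature (e.g. derived
    names that were pruned differently) are skipped.
    """
    k = config.n_clusters
    binary_idx = {name: j for j, name in enumerate(config.binary_features)}
    multi = {m.name: m for m in config.multivalued}
    target = {t.name: t for t in config.targets}
    cols: dict[str, np.ndarray] = {}
    for name in feature_names:
        if name in binary_idx:
            cols[name] = config.binary_profiles[:, binary_idx[name]] > 0.5
        elif name in target:
            cols[name] = np.asarray(target[name].cluster_positive_prob) > 0.5
        elif "=" in name:
            src, level = name.split("=", 1)
            if src in multi and level in multi[src].levels:
                j = multi[src].levels.index(level)
                probs = np.asarray(multi[src].cluster_level_prob)[:, j]
                cols[name] = probs > 0.5
    return pd.DataFrame(cols, index=range(k))


def planted_profile_agreement(
    profiles: Sequence[ClusterProfile],
    ground_truth: pd.Series,
    partition: Partition,
    config: SurveyConfig,
) -> float:
    """Feature-majority agreement between found clusters and planted profiles.

    Each non-suppressed cluster is matched to the planted cluster its
    members mostly came from; agreement is the size-weighted fraction of
    traceable features whose observed majority answer (≥50% yes) equals
    the planted majority for that cluster.
    """
    visible = [p for p in profiles if not p.suppressed]
    if not visible:
        raise ValueError("no non-suppressed clusters to evaluate")
    expected = expected_feature_majority(config, list(visible[0].percentages.index))
    if expected.empty:
        raise ValueError("no traceable features in the profiles")
    agree_weighted = 0.0
    total = 0
    for p in visible:
        members = partition.members(p.cluster)
        truth = ground_truth.loc[members]
        planted = int(truth.mode().iloc[0])
        obs = (p.percentages[expected.columns] >= 50.0).to_numpy()
        exp = expected.loc[planted].to_numpy()
        agree_weighted += (obs == exp).mean() * p.size
        total += p.size
    return agree_weighted / total
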