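"""Cluster composition profiles, privacy suppression, and graph export.

A cluster profile gives, for every feature, the percentage of cluster
members answering positively — the format in which clusterings of
health-survey cohorts are read and compared.  Clusters below a minimum
size (default 10) are flagged *suppressed*: their member-level
composition is withheld from human-readable output to protect
participant identities, and only their sizes are retained in machine
output.

Also here: the recruitment-chain-length check for respondent-driven
sampling (``log_b(n)``, the shortest possible referral chain when every
participant recruits ``b`` others) and lossless GraphML export of a
clustered subject graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .cluster import Partition
from .preprocess import FeatureMatrix

__all__ = [
    "ClusterProfile",
    "profile_clusters",
    "profiles_to_frame",
    "min_chain_length",
    "export_annotated_graph",
    "read_annotated_graph",
]


@dataclass
class ClusterProfile:
    """Positive-response percentages for one cluster."""

    cluster: int
    size: int
    percentages: pd.Series  # feature -> % of members with value 1
    suppressed: bool

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("clusters are nonempty by construction")
        if ((self.percentages < 0) | (self.percentages > 100)).any():
            raise ValueError("percentages must lie in [0, 100]")


def profile_clusters(
    matrix: FeatureMatrix | pd.DataFrame,
    partition: Partition,
    min_size: int = 10,
) -> list[ClusterProfile]:
    """Per-cluster positive percentages with small-cluster suppression.

    ``suppressed`` is True exactly when the cluster has fewer than
    ``min_size`` members; such clusters keep their size but their
    percentages must not be surfaced in human-readable output (the
    writers below honor this).
    """
    frame = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    missing = set(partition.labels) - set(frame.index)
    if missing:
        raise ValueError(f"partition labels {sorted(missing)[:3]}... not in the matrix")
    profiles = []
    for c in range(partition.n_clusters):
        members = partition.members(c)
        sub = frame.loc[members]
        pct = 100.0 * sub.mean(axis=0)
        profiles.append(
            ClusterProfile(
                cluster=c,
                size=len(members),
                percentages=pct,
                suppressed=len(members) < min_size,
            )
        )
    return profiles


def profiles_to_frame(profiles: list[ClusterProfile]) -> pd.DataFrame:
    """Features as rows, non-suppressed clusters as columns (percentages).

    Suppressed clusters are excluded entirely; their existence is
    recorded separately (sizes only) by the pipeline writer.
    """
    visible = [p for p in profiles if not p.suppressed]
    if not visible:
        return pd.DataFrame()
    out = pd.DataFrame({p.cluster: p.percentages.round(1) for p in visible})
    out.columns.name = "cluster"
    return out


def min_chain_length(n_participants: int, branching: int) -> float:
    """Shortest possible recruitment-chain length: ``log_branching(n)``.

    With ``n`` participants each recruiting ``branching`` others, a full
    recruitment tree of depth ``d`` reaches ``branching**d`` people, so
    the chain must be at least ``log_b(n)`` long — the quick check that
    a respondent-driven sample has gone through enough waves to forget
    its seeds.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if branching < 2:
        raise ValueError("branching factor must be at least 2")
    return math.log(n_participants, branching)


def export_annotated_graph(graph: nx.Graph, partition: Partition, path: str | Path) -> None:
    """GraphML with ``subject_id`` and ``cluster`` node attributes."""
    missing = set(graph.nodes) - set(partition.labels)
    if missing:
        raise ValueError(f"partition does not label {sorted(missing)[:3]}...")
    g = nx.Graph(**{k: v for k, v in graph.graph.items() if v is not None})
    for v in graph.nodes:
        g.add_node(str(v), subject_id=str(v), cluster=int(partition.labels[v]))
    for u, v in graph.edges:
        g.add_edge(str(u), str(v))
    try:
        nx.write_graphml(g, path)
    except OSError as exc:
        raise OSError(f"could not write annotated graph to {path}: {exc}") from exc


def read_annotated_graph(path: str | Path) -> tuple[nx.Graph, Partition]:
    try:
        g = nx.read_graphml(path)
    except OSError as exc:
        raise OSError(f"could not read annotated graph from {path}: {exc}") from exc
    labels = {v: int(data["cluster"]) for v, data in g.nodes(data=True)}
    return g, Partition(labels=labels, method=str(g.graph.get("method", "unknown")))
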