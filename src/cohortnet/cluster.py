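"""Graph partitioning: modularity heuristics and node-removal clustering.

Three families of methods are exposed over the same :class:`Partition`
container:

* :func:`louvain` — modularity maximization by local moving plus graph
  aggregation (delegated to :mod:`networkx`);
* :func:`leiden` — Louvain with a refinement phase that guarantees every
  community induces a connected subgraph (delegated to ``leidenalg``);
* :func:`nbr_clust` — node-based-resilience clustering: find a cheap
  attack set under VAT or integrity (see :mod:`cohortnet.resilience`),
  delete it, take the surviving connected components as clusters, and
  finally fold the attack-set nodes back into the neighboring cluster
  they share the most edges with.

All methods decide the number of clusters themselves; none accept a
target cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import networkx as nx

from .resilience import Measure, ResilienceValue, greedy_attack_sets

__all__ = ["Partition", "louvain", "leiden", "nbr_clust", "nbr_clust_both"]


@dataclass
class Partition:
    """A full clustering of a graph's nodes.

    ``labels`` maps every node to a cluster id; ids are contiguous
    integers starting at 0, ordered by decreasing cluster size (ties by
    smallest member) so repeated runs label identically.
    """

    labels: dict
    method: str
    seed: int | None = None
    attack_set: frozenset | None = None
    resilience: ResilienceValue | None = None

    def __post_init__(self) -> None:
        distinct = set(self.labels.values())
        if distinct and distinct != set(range(len(distinct))):
            raise ValueError("cluster labels must be contiguous integers from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster: int) -> list:
        return sorted(v for v, c in self.labels.items() if c == cluster)

    def as_sets(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n_clusters)]
        for v, c in self.labels.items():
            out[c].add(v)
        return out


def _canonical_labels(communities: list[set], method: str, **kw) -> Partition:
    ordered = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    labels = {v: i for i, comm in enumerate(ordered) for v in comm}
    return Partition(labels=labels, method=method, **kw)


def _require_clusterable(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    if graph.number_of_edges() == 0:
        raise ValueError("cannot cluster a graph with no edges")


def louvain(graph: nx.Graph, seed: int = 0) -> Partition:
    """Louvain modularity clustering (resolution fixed at 1.0)."""
    _require_clusterable(graph)
    comms = nx.community.louvain_communities(graph, resolution=1.0, seed=seed)
    return _canonical_labels([set(c) for c in comms], "louvain", seed=seed)


def leiden(graph: nx.Graph, seed: int = 0) -> Partition:
    """Leiden modularity clustering; communities are verified connected."""
    _require_clusterable(graph)
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges])
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, seed=seed, n_iterations=2
    )
    comms = [{nodes[i] for i in comm} for comm in part]
    for comm in comms:  # advertised guarantee of the refinement phase
        if not nx.is_connected(graph.subgraph(comm)):
            raise AssertionError("leiden returned a disconnected community")
    return _canonical_labels(comms, "leiden", seed=seed)


def _reassign_attack_nodes(graph: nx.Graph, comms: list[set], attack: frozenset) -> None:
    """Fold removed nodes back in, by majority of edges to labeled clusters.

    Processes in rounds so a removed node whose neighbors are all
    themselves removed waits until some neighbor has been labeled.  Ties
    go to the larger cluster, then to the lowest cluster index.  A node
    with no labeled neighbor at all (cannot happen on a connected input
    unless every neighbor is in the attack set and unreachable) falls
    back to the largest cluster.
    """
    assigned = {v: i for i, comm in enumerate(comms) for v in comm}
    pending = sorted(attack, key=str)
    while pending:
        progressed = False
        still: list = []
        for v in pending:
            counts: dict[int, int] = {}
            for w in graph.adj[v]:
                if w in assigned:
                    c = assigned[w]
                    counts[c] = counts.get(c, 0) + 1
            if not counts:
                still.append(v)
                continue
            best = max(counts, key=lambda c: (counts[c], len(comms[c]), -c))
            comms[best].add(v)
            assigned[v] = best
            progressed = True
        if not progressed:
            # isolated pocket of attack nodes: dump into the largest cluster
            biggest = max(range(len(comms)), key=lambda c: (len(comms[c]), -c))
            for v in still:
                comms[biggest].add(v)
                assigned[v] = biggest
            still = []
        pending = still


def nbr_clust_both(
    graph: nx.Graph, max_attack_size: int | None = None, seed: int = 0
) -> dict[Measure, Partition]:
    """NBR-Clust under VAT and integrity, sharing one attack-set scan.

    On a disconnected input each component with at least 3 nodes is
    attacked separately (the resilience minimization is independent
    across components) and smaller components become clusters as-is; the
    recorded :class:`~cohortnet.resilience.ResilienceValue` is only
    meaningful for connected inputs and is ``None`` otherwise.
    """
    _require_clusterable(graph)
    components = [set(c) for c in nx.connected_components(graph)]
    attack: dict[Measure, set] = {"integrity": set(), "vat": set()}
    values: dict[Measure, ResilienceValue | None] = {"integrity": None, "vat": None}
    for comp in components:
        if len(comp) < 3 or graph.subgraph(comp).number_of_edges() == 0:
            continue
        comp_values = greedy_attack_sets(graph.subgraph(comp), max_attack_size)
        for measure, rv in comp_values.items():
            attack[measure] |= set(rv.attack_set)
            if len(components) == 1:
                values[measure] = rv

    out: dict[Measure, Partition] = {}
    for measure in ("integrity", "vat"):
        removed = frozenset(attack[measure])
        if len(removed) == graph.number_of_nodes():
            raise ValueError("attack set swallowed the whole graph")
        residual = graph.subgraph(v for v in graph.nodes if v not in removed)
        comms = [set(c) for c in nx.connected_components(residual)]
        comms.sort(key=lambda c: (-len(c), min(map(str, c))))
        _reassign_attack_nodes(graph, comms, removed)
        out[measure] = _canonical_labels(
            comms,
            f"nbr_{measure}",
            seed=seed,
            attack_set=removed,
            resilience=values[measure],
        )
    return out


def nbr_clust(
    graph: nx.Graph,
    measure: Measure,
    max_attack_size: int | None = None,
    seed: int = 0,
) -> Partition:
    """Node-based-resilience clustering with a single measure."""
    return nbr_clust_both(graph, max_attack_size, seed)[measure]
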