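"""Graph resilience measures and attack-set search.

Two resilience measures drive node-removal clustering: *integrity*,

    I(G) = min_{S ⊆ V} ( |S| + C_max(V − S) ),

and *vertex attack tolerance* (VAT),

    VAT(G) = min_{∅ ≠ S ⊂ V} |S| / ( |V| − |S| − C_max(V − S) + 1 ),

where ``S`` is the attack set and ``C_max`` the order of the largest
connected component remaining after deleting ``S``.  A small value of
either measure certifies a cheap attack that shatters the graph; the
minimizing ``S`` is reused by :func:`cohortnet.cluster.nbr_clust` to cut
the graph into clusters.

The empty set is admissible for integrity (giving ``|V|`` on a connected
graph) but excluded for VAT, whose ratio would otherwise be trivially
zero.  Exact minimization is exponential and provided only as a testing
oracle (:func:`brute_force_min`); :func:`greedy_attack_set` is the
practical search, ranking nodes by betweenness centrality recomputed
after each removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import igraph as ig
import networkx as nx

Measure = Literal["vat", "integrity"]

__all__ = [
    "ResilienceValue",
    "integrity_of",
    "vat_of",
    "brute_force_min",
    "greedy_attack_set",
    "greedy_attack_sets",
]


@dataclass(frozen=True)
class ResilienceValue:
    """A resilience measure evaluated at a concrete attack set.

    The defining identity (``value = |S| + cmax`` for integrity,
    ``value = |S| / (n - |S| - cmax + 1)`` for VAT) is re-checked at
    construction time, so a ``ResilienceValue`` cannot encode an
    inconsistent triple.
    """

    measure: Measure
    value: float
    attack_set: frozenset
    cmax: int
    n_nodes: int

    def __post_init__(self) -> None:
        s = len(self.attack_set)
        if self.measure == "integrity":
            expected = s + self.cmax
        elif self.measure == "vat":
            expected = s / (self.n_nodes - s - self.cmax + 1)
        else:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not math.isclose(self.value, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError(
                f"{self.measure} identity violated: value={self.value} "
                f"but |S|={s}, cmax={self.cmax}, n={self.n_nodes} give {expected}"
            )


def _cmax(graph: nx.Graph, removed: set) -> int:
    """Order of the largest connected component of ``graph - removed``."""
    remaining = [v for v in graph.nodes if v not in removed]
    if not remaining:
        return 0
    seen: set = set()
    best = 0
    for start in remaining:
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for w in graph.adj[u]:
                if w not in removed and w not in seen:
                    seen.add(w)
                    stack.append(w)
        best = max(best, size)
    return best


def integrity_of(graph: nx.Graph, attack_set: Iterable) -> ResilienceValue:
    """Evaluate ``|S| + C_max(V − S)`` for a given attack set ``S``."""
    s = frozenset(attack_set)
    if not s <= set(graph.nodes):
        raise ValueError("attack set must be a subset of the graph's nodes")
    cmax = _cmax(graph, set(s))
    return ResilienceValue("integrity", len(s) + cmax, s, cmax, graph.number_of_nodes())


def vat_of(graph: nx.Graph, attack_set: Iterable) -> ResilienceValue:
    """Evaluate the VAT ratio for a given nonempty proper attack set."""
    s = frozenset(attack_set)
    n = graph.number_of_nodes()
    if not s:
        raise ValueError("VAT is undefined for the empty attack set")
    if not s <= set(graph.nodes):
        raise ValueError("attack set must be a subset of the graph's nodes")
    if len(s) >= n:
        raise ValueError("VAT requires a strict subset of the nodes")
    cmax = _cmax(graph, set(s))
    value = len(s) / (n - len(s) - cmax + 1)
    return ResilienceValue("vat", value, s, cmax, n)


_EVALUATE = {"integrity": integrity_of, "vat": vat_of}


def brute_force_min(graph: nx.Graph, measure: Measure) -> ResilienceValue:
    """Exact minimum of a resilience measure by subset enumeration.

    Testing oracle only: refuses graphs with more than 15 nodes.  Ties
    are broken toward the smallest attack set, then lexicographically by
    the sorted node tuple, so the result is deterministic.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n > 15:
        raise ValueError(f"brute force limited to 15 nodes, got {n}")
    if measure not in _EVALUATE:
        raise ValueError(f"unknown measure {measure!r}")

    best: ResilienceValue | None = None
    best_key: tuple | None = None
    for mask in range(2**n):
        size = mask.bit_count()
        if measure == "vat" and (size == 0 or size == n):
            continue
        subset = frozenset(nodes[i] for i in range(n) if mask >> i & 1)
        rv = _EVALUATE[measure](graph, subset)
        key = (rv.value, size, tuple(sorted(map(str, subset))))
        if best_key is None or key < best_key:
            best, best_key = rv, key
    assert best is not None
    return best


@dataclass
class _AttackScan:
    """Betweenness-ordered removal sequence with per-prefix C_max values.

    ``order[:j]`` is the j-th candidate attack set; ``cmax_after[j]`` is
    the largest remaining component once those j nodes are deleted
    (``cmax_after[0]`` refers to the intact graph).
    """

    order: list = field(default_factory=list)
    cmax_after: list[int] = field(default_factory=list)


def _scan_attack_prefixes(graph: nx.Graph, max_size: int | None = None) -> _AttackScan:
    """Greedily delete the current highest-betweenness node, recording C_max.

    Betweenness is recomputed on the residual graph after every removal
    (igraph's C implementation; exact, unweighted).  Ties are broken by
    node order, so the scan is deterministic.  The prefix length is
    capped at ``ceil(n/4)`` by default to keep the search tractable on
    pipeline-sized graphs.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if max_size is None:
        max_size = math.ceil(n / 4)
    max_size = min(max_size, n - 1)

    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=n, edges=[(index[u], index[v]) for u, v in graph.edges])

    scan = _AttackScan()
    alive = list(range(n))  # igraph re-indexes on deletion; track original ids
    scan.cmax_after.append(max(g.connected_components().sizes(), default=0))
    for _ in range(max_size):
        bt = g.betweenness()
        # ties → lowest original node id (alive[] is kept sorted by original id)
        best_pos = max(range(len(bt)), key=lambda i: (bt[i], -i))
        scan.order.append(nodes[alive[best_pos]])
        g.delete_vertices([best_pos])
        del alive[best_pos]
        scan.cmax_after.append(max(g.connected_components().sizes(), default=0))
    return scan


def _best_prefix(scan: _AttackScan, measure: Measure, n: int) -> tuple[int, float, int]:
    start = 1 if measure == "vat" else 0
    best: tuple[float, int] | None = None
    for j in range(start, len(scan.cmax_after)):
        cmax = scan.cmax_after[j]
        if measure == "integrity":
            value = float(j + cmax)
        else:
            value = j / (n - j - cmax + 1)
        if best is None or value < best[0]:
            best = (value, j)
    assert best is not None
    return best[1], best[0], scan.cmax_after[best[1]]


def greedy_attack_sets(
    graph: nx.Graph, max_size: int | None = None
) -> dict[Measure, ResilienceValue]:
    """Greedy attack sets for both measures from one betweenness scan.

    The removal sequence does not depend on the measure, only the chosen
    prefix length does, so both minimizations share a single (expensive)
    scan.  Each returned value is an upper bound on the exact minimum.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("greedy attack-set search needs at least 3 nodes")
    if not nx.is_connected(graph):
        raise ValueError("greedy attack-set search expects a connected graph")
    scan = _scan_attack_prefixes(graph, max_size)
    out: dict[Measure, ResilienceValue] = {}
    for measure in ("integrity", "vat"):
        j, value, cmax = _best_prefix(scan, measure, n)
        out[measure] = ResilienceValue(
            measure, value, frozenset(scan.order[:j]), cmax, n
        )
    return out


def greedy_attack_set(
    graph: nx.Graph, measure: Measure, max_size: int | None = None
) -> ResilienceValue:
    """Approximate minimizer of one resilience measure (see module docs)."""
    if measure not in _EVALUATE:
        raise ValueError(f"unknown measure {measure!r}")
    return greedy_attack_sets(graph, max_size)[measure]
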