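"""Cohesiveness-based hub extraction (greedy overlapping clustering).

A hub is a protein set V' scored by its cohesiveness

    f(V') = w_in / (w_in + w_bound + p * |V'|)

where ``w_in`` is the total weight of edges with both ends in V', ``w_bound``
the total weight of edges with exactly one end in V', and ``p`` a per-member
penalty modelling unobserved interactions.  Clusters are grown greedily from
high-degree seeds by the single best add-a-boundary-node or remove-a-member
step that strictly increases cohesiveness, merged when their overlap score
ω(A,B) = |A∩B|²/(|A|·|B|) exceeds a threshold, filtered by size and density,
and ranked.  Parameter defaults follow the published defaults of the
ClusterONE algorithm this mirrors (p=2, ω=0.8, min size 3, min density 0.3).

Ranking is by cohesiveness (ties: larger size, then lexicographically
smallest member) rather than a one-sided quality p-value: deterministic and
monotone in the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core_io import InteractionGraph, logger


@dataclass(frozen=True)
class ClusterParams:
    penalty: float = 2.0
    overlap_threshold: float = 0.8
    min_size: int = 3
    min_density: float = 0.3

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError("overlap threshold must be in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min hub size must be >= 1")
        if not 0.0 <= self.min_density <= 1.0:
            raise ValueError("min density must be in [0, 1]")


@dataclass
class Hub:
    members: set[str]
    cohesiveness: float
    w_in: float
    w_bound: float
    rank: int = 0
    metal: str = ""
    pd_members: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def hub_id(self) -> str:
        return f"{self.metal or 'hub'}:{min(self.members)}" if self.members else "empty"


def _boundary_weights(g: nx.Graph, members: set[str]) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, attr in g[u].items():
            w = attr.get("weight", 1.0)
            if v in members:
                if u < v:       # count internal edges once
                    w_in += w
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(graph: InteractionGraph, members: set[str],
                 penalty: float = 2.0) -> float:
    """f(V') = w_in / (w_in + w_bound + p·|V'|); 0 when the denominator is 0."""
    if not members:
        raise ValueError("empty member set")
    missing = members - graph.nodes
    if missing:
        raise ValueError(f"members not in graph: {sorted(missing)}")
    w_in, w_bound = _boundary_weights(graph.graph, members)
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _grow(g: nx.Graph, seed: str, params: ClusterParams) -> tuple[set[str], float, float, float]:
    members = {seed}
    w_in, w_bound = _boundary_weights(g, members)
    p = params.penalty

    def score(wi: float, wb: float, size: int) -> float:
        denom = wi + wb + p * size
        return wi / denom if denom > 0 else 0.0

    current = score(w_in, w_bound, 1)
    while True:
        best: tuple[float, str, str] | None = None   # (new_score, node, action)
        boundary: set[str] = set()
        for u in members:
            boundary.update(v for v in g[u] if v not in members)
        for v in sorted(boundary):
            w_to_members = sum(a.get("weight", 1.0) for t, a in g[v].items() if t in members)
            w_to_outside = sum(a.get("weight", 1.0) for t, a in g[v].items() if t not in members)
            s = score(w_in + w_to_members,
                      w_bound - w_to_members + w_to_outside,
                      len(members) + 1)
            if s > current + 1e-12 and (best is None or s > best[0] + 1e-12):
                best = (s, v, "add")
        if len(members) > 1:
            for u in sorted(members):
                w_to_members = sum(a.get("weight", 1.0) for t, a in g[u].items() if t in members)
                w_to_outside = sum(a.get("weight", 1.0) for t, a in g[u].items() if t not in members)
                s = score(w_in - w_to_members,
                          w_bound + w_to_members - w_to_outside,
                          len(members) - 1)
                if s > current + 1e-12 and (best is None or s > best[0] + 1e-12):
                    best = (s, u, "remove")
        if best is None:
            break
        s, node, action = best
        w_node_members = sum(a.get("weight", 1.0) for t, a in g[node].items()
                             if t in members and t != node)
        w_node_outside = sum(a.get("weight", 1.0) for t, a in g[node].items()
                             if t not in members)
        if action == "add":
            w_in += w_node_members
            w_bound += w_node_outside - w_node_members
            members.add(node)
        else:
            members.remove(node)
            w_node_members = sum(a.get("weight", 1.0) for t, a in g[node].items()
                                 if t in members)
            w_node_outside = sum(a.get("weight", 1.0) for t, a in g[node].items()
                                 if t not in members)
            w_in -= w_node_members
            w_bound += w_node_members - w_node_outside
        current = s
    return members, current, w_in, w_bound


def grow_cluster(graph: InteractionGraph, seed: str,
                 params: ClusterParams = ClusterParams()) -> Hub:
    """Greedy hill-climb from a single seed to a cohesiveness local optimum.

    Ties between equally good moves break lexicographically on node name
    (adds examined before removes), so the result is deterministic.
    """
    if seed not in graph.nodes:
        raise ValueError(f"seed {seed!r} not in graph")
    members, coh, w_in, w_bound = _grow(graph.graph, seed, params)
    return Hub(members=members, cohesiveness=coh, w_in=w_in, w_bound=w_bound)


def overlap_score(a: set[str], b: set[str]) -> float:
    """ω(A,B) = |A∩B|² / (|A|·|B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b)) if a and b else 0.0


def _density(g: nx.Graph, members: set[str]) -> float:
    k = len(members)
    if k < 2:
        return 0.0
    e = g.subgraph(members).number_of_edges()
    return 2.0 * e / (k * (k - 1))


def find_hubs(graph: InteractionGraph,
              params: ClusterParams = ClusterParams(),
              metal: str = "") -> list[Hub]:
    """Full decomposition of a network into ranked cohesive hubs.

    Seeds are processed in decreasing degree order (ties lexicographic),
    skipping nodes already covered by a grown cluster.  Overlapping clusters
    (ω over threshold) are merged by transitive-closure union, then filtered
    by minimum size and internal density, scored, and ranked.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    order = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
    covered: set[str] = set()
    clusters: list[set[str]] = []
    for seed in order:
        if seed in covered:
            continue
        members, _, _, _ = _grow(g, seed, params)
        clusters.append(members)
        covered |= members
    # transitive-closure merge over the overlap graph
    merged = [set(c) for c in clusters]
    changed = True
    while changed:
        changed = False
        out: list[set[str]] = []
        for c in merged:
            hit = None
            for existing in out:
                if overlap_score(c, existing) > params.overlap_threshold:
                    hit = existing
                    break
            if hit is not None:
                hit |= c
                changed = True
            else:
                out.append(c)
        merged = out
    hubs: list[Hub] = []
    for members in merged:
        if len(members) < params.min_size:
            continue
        if _density(g, members) < params.min_density:
            continue
        w_in, w_bound = _boundary_weights(g, members)
        denom = w_in + w_bound + params.penalty * len(members)
        coh = w_in / denom if denom > 0 else 0.0
        hubs.append(Hub(members=members, cohesiveness=coh,
                        w_in=w_in, w_bound=w_bound, metal=metal))
    hubs.sort(key=lambda h: (-h.cohesiveness, -h.size, min(h.members)))
    for i, h in enumerate(hubs, start=1):
        h.rank = i
    logger.debug("find_hubs(%s): %d cluster(s) grown, %d hub(s) kept",
                 graph.name, len(clusters), len(hubs))
    return hubs


def select_top_hub(hubs: list[Hub], metal: str = "") -> Hub:
    """The rank-1 hub; raises (naming the metal) when the list is empty."""
    if not hubs:
        raise ValueError(f"no hub found for metal {metal or '?'}")
    return hubs[0]
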