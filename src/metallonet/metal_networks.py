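"""Metal protein networks, Erdős–Rényi nulls and pathway comparison networks.

A metal protein network (metal-PN) is built from all proteins binding a given
metal (the seeds) by first-neighbor expansion in a reference interactome:
nodes are the seeds present in the interactome plus their immediate
interaction partners; edges are, by default, all reference edges induced on
that node set.  Pathway networks use the same construction on pathway
members, and node/edge-matched random graphs serve as the null class.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .core_io import InteractionGraph, MetalProteinTable, logger

MIN_GROUP_SIZE = 10  # minimum binding proteins for a metal group to be kept


@dataclass
class MetalPN:
    """One metal's protein network plus bookkeeping."""

    metal: str
    seeds: set[str]              # metal-binding proteins found in the interactome
    graph: InteractionGraph
    missing_seeds: set[str]      # annotated proteins absent from the interactome


def group_by_metal(annotations: MetalProteinTable,
                   min_size: int = MIN_GROUP_SIZE) -> MetalProteinTable:
    """Keep only metal groups with at least ``min_size`` binding proteins.

    Multi-metal proteins stay in every surviving group.
    """
    if not annotations.entries:
        raise ValueError("empty metal-protein table")
    kept = {m: set(ps) for m, ps in annotations.entries.items() if len(ps) >= min_size}
    dropped = sorted(set(annotations.entries) - set(kept))
    if dropped:
        logger.info("dropped %d metal group(s) below size %d: %s",
                    len(dropped), min_size, ", ".join(dropped))
    if not kept:
        logger.warning("no metal group survives the size filter")
    return MetalProteinTable(entries=kept)


def _first_neighbor_expand(seeds: set[str], ppi: InteractionGraph,
                           star_only: bool) -> nx.Graph:
    g = ppi.graph
    present = seeds & set(g.nodes)
    nodes = set(present)
    for s in present:
        nodes.update(g.neighbors(s))
    if star_only:
        # keep only seed-incident edges (star reading of the expansion rule)
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        for s in present:
            for nb in g.neighbors(s):
                sub.add_edge(s, nb, weight=g[s][nb].get("weight", 1.0))
        return sub
    return nx.Graph(g.subgraph(nodes))


def build_metal_pn(metal: str, seeds: set[str], ppi: InteractionGraph,
                   star_only: bool = False) -> MetalPN:
    """First-neighbor expansion of a metal's binding proteins.

    Seeds absent from the interactome are reported, not silently dropped;
    if none is present the metal cannot form a network and this raises.
    """
    if ppi.n_nodes() == 0:
        raise ValueError("reference interactome is empty")
    seeds = {str(s).strip().upper() for s in seeds}
    present = seeds & ppi.nodes
    missing = seeds - present
    if not present:
        raise ValueError(f"no binding protein of metal {metal!r} is present "
                         f"in the interactome")
    if missing:
        logger.info("metal %s: %d seed(s) absent from the interactome: %s",
                    metal, len(missing), ", ".join(sorted(missing)))
    sub = _first_neighbor_expand(seeds, ppi, star_only)
    graph = InteractionGraph(graph=sub, label="metal", name=f"metalPN_{metal}")
    return MetalPN(metal=metal, seeds=present, graph=graph, missing_seeds=missing)


def build_all_metal_pns(annotations: MetalProteinTable, ppi: InteractionGraph,
                        min_size: int = MIN_GROUP_SIZE,
                        star_only: bool = False) -> list[MetalPN]:
    grouped = group_by_metal(annotations, min_size=min_size)
    return [build_metal_pn(m, grouped.entries[m], ppi, star_only=star_only)
            for m in grouped.metals]


def generate_er_null(n_nodes: int, target_edges: int, seed: int,
                     name: str = "") -> InteractionGraph:
    """G(n, M): uniformly random simple graph with exactly ``target_edges`` edges."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= target_edges <= max_edges:
        raise ValueError(f"target_edges {target_edges} infeasible for "
                         f"{n_nodes} nodes (max {max_edges})")
    g = nx.gnm_random_graph(n_nodes, target_edges, seed=seed)
    g = nx.relabel_nodes(g, {i: f"R{i:04d}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return InteractionGraph(graph=g, label="random", name=name or f"ER_n{n_nodes}_m{target_edges}")


def generate_er_null_gnp(n_nodes: int, p: float, seed: int,
                         name: str = "") -> InteractionGraph:
    """G(n, p) null matched on node count only, with p set by the caller
    (typically the density of the network being nulled)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"R{i:04d}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return InteractionGraph(graph=g, label="random", name=name or f"ER_n{n_nodes}_p{p:g}")


def null_for(network: InteractionGraph, seed: int,
             match_edges: bool = True) -> InteractionGraph:
    """ER null matched to ``network``: nodes and edges (default), or nodes
    only with p equal to the network's density."""
    n = network.n_nodes()
    if match_edges:
        return generate_er_null(n, network.n_edges(), seed,
                                name=f"null_{network.name}")
    density = nx.density(network.graph) if n > 1 else 0.0
    return generate_er_null_gnp(n, density, seed, name=f"null_{network.name}")


def build_pathway_network(pathway_genes: set[str],
                          ppi: InteractionGraph,
                          name: str = "pathway",
                          star_only: bool = False) -> InteractionGraph:
    """Same first-neighbor expansion as a metal-PN, seeded by pathway members."""
    if not pathway_genes:
        raise ValueError("empty pathway gene set")
    genes = {str(g).strip().upper() for g in pathway_genes}
    present = genes & ppi.nodes
    if not present:
        raise ValueError(f"no member of pathway {name!r} is present in the interactome")
    sub = _first_neighbor_expand(genes, ppi, star_only)
    return InteractionGraph(graph=sub, label="pathway", name=name)
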