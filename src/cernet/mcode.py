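"""Molecular-complex detection (MCODE) for functional-module extraction.

The algorithm follows the seed-and-expand scheme of Bader & Hogue: every
vertex is weighted by the density of the highest k-core of its closed
neighborhood times that core's k; complexes are grown greedily from the
highest-weight unvisited vertex, admitting neighbors whose weight is within
``node_score_cutoff`` of the seed weight; an optional 2-core "haircut"
removes tree-like fringes.  A module's score is its density times its size,
and only modules above ``min_module_score`` are reported.  Iteration order is
fixed (weight descending, then lexicographic node id), so output is
deterministic, and modules are vertex-disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["McodeParams", "ModuleResult", "vertex_weight", "find_modules", "module_score"]


@dataclass
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    min_module_score: float = 5.0
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValueError("node_score_cutoff must be in [0, 1]")


@dataclass
class ModuleResult:
    nodes: set
    score: float
    seed_node: str


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weight(net: nx.Graph, node, degree_cutoff: int = 2) -> float:
    """k × density of the highest k-core of the node's closed neighborhood.

    Vertices below ``degree_cutoff`` get weight 0 (e.g. an isolated node or a
    pendant under the default cutoff of 2).  For a node inside K4 the closed
    neighborhood is K4 itself: highest core k = 3 with density 1, weight 3.
    """
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    if net.degree(node) < degree_cutoff:
        return 0.0
    closed = set(net.neighbors(node)) | {node}
    h = net.subgraph(closed)
    cores = nx.core_number(h)
    kmax = max(cores.values())
    if kmax == 0:
        return 0.0
    core_nodes = [n for n, k in cores.items() if k >= kmax]
    return kmax * _density(net.subgraph(core_nodes))


def module_score(net: nx.Graph, nodes) -> float:
    """Density × node count of the induced subgraph."""
    sub = net.subgraph(nodes)
    return _density(sub) * sub.number_of_nodes()


def find_modules(net: nx.Graph, params: McodeParams | None = None) -> list[ModuleResult]:
    """Greedy MCODE complex prediction; modules are vertex-disjoint.

    Returns modules with score strictly above ``params.min_module_score``,
    sorted by score descending (ties by seed id).
    """
    params = params or McodeParams()
    if net.number_of_nodes() == 0:
        return []
    weights = {n: vertex_weight(net, n, params.degree_cutoff) for n in net.nodes}
    order = sorted(weights, key=lambda n: (-weights[n], str(n)))
    visited: set = set()
    modules: list[ModuleResult] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        member = {seed}
        frontier = [(seed, 0)]
        while frontier:
            node, depth = frontier.pop(0)
            if depth >= params.max_depth:
                continue
            for nb in sorted(net.neighbors(node), key=str):
                if nb in visited or nb in member:
                    continue
                if weights[nb] >= threshold:
                    member.add(nb)
                    frontier.append((nb, depth + 1))
        visited |= member
        nodes = set(member)
        if params.haircut and params.k_core > 0:
            nodes = set(nx.k_core(net.subgraph(nodes), k=params.k_core).nodes)
        if params.fluff:
            fringe = set()
            for n in nodes:
                closed = set(net.neighbors(n)) | {n}
                if _density(net.subgraph(closed)) > params.node_score_cutoff:
                    fringe |= set(net.neighbors(n)) - visited
            nodes |= fringe
            visited |= fringe
        if not nodes:
            continue
        sub = net.subgraph(nodes)
        if not nx.is_connected(sub):
            # keep the seed's component (haircut can disconnect fringes)
            for comp in nx.connected_components(sub):
                if seed in comp:
                    nodes = set(comp)
                    break
            else:
                nodes = set(max(nx.connected_components(sub), key=len))
        score = module_score(net, nodes)
        if score > params.min_module_score:
            modules.append(ModuleResult(nodes=nodes, score=score, seed_node=str(seed)))
    modules.sort(key=lambda m: (-m.score, m.seed_node))
    return modules
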