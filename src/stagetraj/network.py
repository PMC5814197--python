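"""Protein-interaction graphs: construction, module detection, hubs, chains.

Edge tables in the STRING detailed-scores dialect are filtered on a single
evidence channel (default: the ``experimental`` channel with any positive
score) to keep only experimentally supported links. Module detection
re-implements the molecular-complex-detection scheme built on k-cores:
every vertex is weighted by ``k * density`` of the highest k-core of its
closed neighborhood, and complexes are grown greedily from high-weight
seeds, keeping neighbors whose weight is within a fraction (the vertex
weight percentage, VWP) of the seed's. Hub subnetworks collect nodes whose
degree in the parent graph falls in a configured range, and a deterministic
"key chain" — the simple path through the hub subgraph maximizing total
parent degree — stands in for a manual hierarchical-layout reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .enrichment import GeneAnnotation
from .io import FormatError
from .trajectory import TrajectoryResult

MAX_CHAIN_NODES = 25


class SizeGuardError(ValueError):
    """Hub set too large for exhaustive chain search; tighten the degree range."""


def read_interactions(
    edges: pd.DataFrame,
    channel: str = "experimental",
    min_channel_score: int = 1,
) -> nx.Graph:
    """Build an undirected graph from a STRING-dialect edge table.

    Keeps edges whose ``channel`` score is >= ``min_channel_score``;
    symmetric duplicates collapse to one undirected edge (the maximum score
    per channel is retained) and self-loops are dropped.
    """
    for col in ("protein1", "protein2", channel, "combined_score"):
        if col not in edges.columns:
            raise FormatError(f"interaction table lacks column {col!r}")
    g = nx.Graph()
    kept = edges[edges[channel] >= min_channel_score]
    for row in kept.itertuples(index=False):
        u, v = row.protein1, row.protein2
        if u == v:
            continue
        attrs = {
            channel: int(getattr(row, channel)),
            "combined_score": int(row.combined_score),
        }
        if g.has_edge(u, v):
            for key, val in attrs.items():
                g[u][v][key] = max(g[u][v].get(key, 0), val)
        else:
            g.add_edge(u, v, **attrs)
    return g


def induce(graph: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subgraph on the given genes (intersected with the node set)."""
    return graph.subgraph(set(genes) & set(graph.nodes)).copy()


def remove_term_nodes(
    graph: nx.Graph, annotation: GeneAnnotation, term: str
) -> nx.Graph:
    """Drop nodes annotated with ``term`` together with their edges."""
    carriers = annotation.genes_with(term)  # raises on unknown term
    g = graph.copy()
    g.remove_nodes_from([n for n in graph.nodes if n in carriers])
    return g


def _density(g: nx.Graph) -> float:
    v = g.number_of_nodes()
    if v < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (v * (v - 1))


def mcode_weights(graph: nx.Graph) -> dict[str, float]:
    """Vertex weight = k * density of the top k-core of the closed neighborhood.

    An isolated vertex has weight 0. For a vertex of a (k+1)-clique the
    closed neighborhood is the clique itself, whose highest core is the
    k-core with density 1, giving weight k.
    """
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbhd = graph.subgraph(set(graph[v]) | {v})
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_nums = nx.core_number(nbhd)
        kmax = max(core_nums.values())
        top_core = nbhd.subgraph([u for u, c in core_nums.items() if c >= kmax])
        weights[v] = kmax * _density(top_core)
    return weights


@dataclass(frozen=True)
class Module:
    """A detected complex: members, seed, density and score = density * size."""

    members: frozenset[str]
    seed: str
    density: float
    score: float

    @property
    def size(self) -> int:
        return len(self.members)


def _has_two_core(g: nx.Graph) -> bool:
    return nx.k_core(g, k=2).number_of_nodes() > 0


def mcode_modules(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_threshold: float = 0.2,
) -> list[Module]:
    """Greedy complex growth from high-weight seeds.

    Vertices are visited in descending weight order (ties by node id). From
    each unvisited seed, neighbors are recursively included while their
    weight is >= ``seed_weight * (1 - vwp)``; each vertex joins at most one
    module. Modules without a 2-core are discarded. ``haircut`` iteratively
    strips members of within-module degree 1; ``fluff`` adds outside
    neighbors whose closed-neighborhood density exceeds the threshold
    (fluffed nodes may overlap between modules). Ranking: score = density *
    size descending, then size descending, then seed id.
    """
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must lie in [0, 1)")
    weights = mcode_weights(graph)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    modules: list[Module] = []

    for seed in order:
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            current = frontier.pop()
            for nb in sorted(graph[current]):
                if nb in assigned or nb in members:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    frontier.append(nb)
        assigned |= members

        sub = graph.subgraph(members)
        if not _has_two_core(sub):
            continue
        if haircut:
            sub = sub.copy()
            while True:
                leaves = [v for v, d in sub.degree() if d <= 1]
                if not leaves:
                    break
                sub.remove_nodes_from(leaves)
            members = set(sub.nodes)
            if not members:
                continue
        if fluff:
            extra = set()
            for v in sorted(members):
                for nb in graph[v]:
                    if nb in members or nb in extra:
                        continue
                    closed = graph.subgraph(set(graph[nb]) | {nb})
                    if _density(closed) > fluff_threshold:
                        extra.add(nb)
            members |= extra
        final = graph.subgraph(members)
        dens = _density(final)
        modules.append(
            Module(
                members=frozenset(members),
                seed=seed,
                density=dens,
                score=dens * len(members),
            )
        )

    return sorted(modules, key=lambda m: (-m.score, -m.size, m.seed))


@dataclass(frozen=True)
class HubNetwork:
    """Nodes whose parent-graph degree lies in [lo, hi], with induced edges."""

    graph: nx.Graph  # induced subgraph on the hubs
    parent_degree: dict[str, int]
    degree_lo: int
    degree_hi: int


def hub_subnetwork(graph: nx.Graph, degree_lo: int, degree_hi: int) -> HubNetwork:
    """Extract the degree-ranged hub subnetwork of a graph."""
    if degree_lo < 0 or degree_lo > degree_hi:
        raise ValueError("need 0 <= degree_lo <= degree_hi")
    degrees = dict(graph.degree())
    hubs = [v for v, d in degrees.items() if degree_lo <= d <= degree_hi]
    return HubNetwork(
        graph=graph.subgraph(hubs).copy(),
        parent_degree={v: degrees[v] for v in hubs},
        degree_lo=degree_lo,
        degree_hi=degree_hi,
    )


def key_chain(hub: HubNetwork) -> list[str]:
    """Simple path through the hub subgraph maximizing total parent degree.

    Exhaustive branch-and-bound over simple paths; ties prefer the longer
    path, then the lexicographically smallest node sequence. Guarded to
    subgraphs of <= 25 nodes — tighten the hub degree range for larger sets.
    """
    g = hub.graph
    if g.number_of_nodes() == 0:
        raise ValueError("hub subnetwork is empty")
    if g.number_of_nodes() > MAX_CHAIN_NODES:
        raise SizeGuardError(
            f"{g.number_of_nodes()} hub nodes exceed the exhaustive-search "
            f"limit of {MAX_CHAIN_NODES}; use a tighter degree range"
        )
    w = hub.parent_degree
    total = sum(w.values())

    best: list = [-1.0, 0, None]  # [sum, length, sequence]

    def better(cand_sum, cand_path):
        if cand_sum > best[0]:
            return True
        if cand_sum < best[0]:
            return False
        if len(cand_path) != best[1]:
            return len(cand_path) > best[1]
        return cand_path < best[2]

    def dfs(path, used, cur_sum, remaining):
        if better(cur_sum, path):
            best[0], best[1], best[2] = cur_sum, len(path), list(path)
        if cur_sum + remaining < best[0]:
            return
        for nb in sorted(g[path[-1]]):
            if nb in used:
                continue
            path.append(nb)
            used.add(nb)
            dfs(path, used, cur_sum + w[nb], remaining - w[nb])
            used.remove(nb)
            path.pop()

    for start in sorted(g.nodes):
        dfs([start], {start}, w[start], total - w[start])
    return best[2]


def annotate_stage(
    graph: nx.Graph, trajectories: Sequence[TrajectoryResult] | TrajectoryResult
) -> nx.Graph:
    """Label nodes with their deviation stage and screen direction.

    A node in some deviated set D_k gets ``stage`` = the label D_k is
    attached to; a node continuing through the final stage gets
    ``"persistent"``; everything else ``"unclassified"``.
    """
    if isinstance(trajectories, TrajectoryResult):
        trajectories = [trajectories]
    g = graph.copy()
    nx.set_node_attributes(g, "unclassified", "stage")
    nx.set_node_attributes(g, "none", "direction")
    for traj in trajectories:
        for label, dev in zip(traj.stage_labels, traj.deviated):
            for gene in dev:
                if gene in g:
                    g.nodes[gene]["stage"] = label
                    g.nodes[gene]["direction"] = traj.direction
        for gene in traj.persistent:
            if gene in g:
                g.nodes[gene]["stage"] = "persistent"
                g.nodes[gene]["direction"] = traj.direction
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def modules_table(modules: list[Module]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(modules) + 1),
            "score": [m.score for m in modules],
            "size": [m.size for m in modules],
            "seed": [m.seed for m in modules],
            "members": [",".join(sorted(m.members)) for m in modules],
        }
    )
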